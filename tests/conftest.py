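import numpy as np
import pandas as pd
import pytest

from annogs.io import GenotypeMatrix, PhenotypeVector, SnpTable
from annogs.simulate import SimConfig, simulate_cohort


def random_genotypes(n, p, seed=0, prefix="s"):
    """Plain random genotype matrix with minimal SNP metadata."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, p)
    codes = rng.binomial(2, maf, size=(n, p))
    rows = [(f"{prefix}{j}", "chr1", 100 + j, "A", "G", "noncoding", False)
            for j in range(p)]
    snps = SnpTable(pd.DataFrame(rows, columns=list(SnpTable.REQUIRED)))
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps, codes)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared by read-only tests."""
    cfg = SimConfig(
        n_samples=250,
        n_noncoding_snps=160,
        n_coding_snps=40,
        n_elements=40,
        n_genes=16,
        n_terms=12,
        n_metaterms=4,
        n_causal_elements=10,
        n_causal_coding=4,
        heritability_target=0.5,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def phenotype_for(small_cohort):
    return small_cohort[3]
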