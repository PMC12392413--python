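"""Synthetic cohort generator with a known genotype -> annotation -> phenotype cascade.

The generator emulates the statistical structure of a livestock resequencing
cohort: sparse causal SNPs sitting inside cis-regulatory elements, an
annotation-mediated effect cascade (element -> gene -> functional term ->
metaterm module), allele-level impact scores whose deltas are large for causal
variants and near zero otherwise, and environmental noise scaled to a target
heritability.  Everything downstream (network masks, Bayesian SNP classes,
interpretability tracing) can therefore be tested against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import (
    AnnotationBundle,
    GenotypeMatrix,
    ImpactScores,
    PhenotypeVector,
    SnpTable,
)

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "write_cohort"]

# BayesR-style effect-size classes: variances as fractions of a unit genetic
# variance (null / small / medium / large).
MIXTURE_SCALES = (0.0, 1e-4, 1e-3, 1e-2)

_ELEMENT_LEN = 600
_ELEMENT_SPACING = 2_000
_GENE_LEN = 20_000


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int = 1000
    n_noncoding_snps: int = 800
    n_coding_snps: int = 200
    n_elements: int = 200
    n_genes: int = 60
    n_terms: int = 40
    n_metaterms: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_elements: int = 20
    n_causal_coding: int = 10
    heritability_target: float = 0.4
    interaction_fraction: float = 0.0
    seed: int = 0
    # probabilities of the small/medium/large effect classes for causal SNPs
    mixture_probs: tuple[float, float, float] = (0.4, 0.35, 0.25)
    # optional adjacent-SNP LD (latent AR(1) copula correlation); 0 = linkage
    # equilibrium
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        counts = (
            self.n_samples, self.n_noncoding_snps, self.n_coding_snps,
            self.n_elements, self.n_genes, self.n_terms, self.n_metaterms,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all entity counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 <= self.heritability_target < 1):
            raise ValueError("heritability_target must lie in [0, 1)")
        if not (0 <= self.interaction_fraction <= 1):
            raise ValueError("interaction_fraction must lie in [0, 1]")
        if self.n_causal_elements > self.n_elements:
            raise ValueError(
                f"cannot place {self.n_causal_elements} causal elements in "
                f"{self.n_elements} elements"
            )
        if self.n_causal_coding > self.n_coding_snps:
            raise ValueError("more causal coding SNPs requested than coding SNPs")


@dataclass
class SimTruth:
    """Ground truth of the causal cascade for recovery tests."""

    causal_snp_ids: list[str]
    effects: pd.Series  # additive effect per causal SNP
    causal_gene_ids: list[str]
    causal_term_ids: list[str]
    causal_metaterm_ids: list[str]
    realized_heritability: float
    interactions: list[tuple[str, str, float]] = field(default_factory=list)


def _simulate_genotypes(cfg: SimConfig, maf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = len(maf)
    if cfg.ld_rho <= 0:
        return rng.binomial(2, maf, size=(cfg.n_samples, p))
    # latent AR(1) Gaussian copula over adjacent SNPs, two haplotype draws
    rho = cfg.ld_rho
    codes = np.zeros((cfg.n_samples, p), dtype=int)
    thresh = norm.ppf(maf)
    for _ in range(2):
        z = np.empty((cfg.n_samples, p))
        z[:, 0] = rng.standard_normal(cfg.n_samples)
        eps = rng.standard_normal((cfg.n_samples, p - 1))
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j - 1]
        codes += (z < thresh).astype(int)
    return codes


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, AnnotationBundle, ImpactScores, PhenotypeVector, SimTruth]:
    """Generate a complete cohort; identical config + seed is bit-identical."""
    rng = np.random.default_rng(cfg.seed)

    # --- genomic layout (one chromosome, deterministic coordinates) ---------
    el_starts = 50_000 + np.arange(cfg.n_elements) * _ELEMENT_SPACING
    elements = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": el_starts,
            "end": el_starts + _ELEMENT_LEN,
            "label": [f"EL{e}" for e in range(cfg.n_elements)],
        }
    )
    span = int(el_starts[-1]) + _ELEMENT_LEN + 100_000
    gene_starts = np.linspace(40_000, span, cfg.n_genes, dtype=int)
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": gene_starts,
            "end": gene_starts + _GENE_LEN,
            "gene_id": [f"G{g}" for g in range(cfg.n_genes)],
        }
    )

    # element -> nearest gene within the +-1 Mb cis window
    el_mid = (elements["start"] + elements["end"]).to_numpy() // 2
    g_mid = (genes["start"] + genes["end"]).to_numpy() // 2
    nearest = np.abs(el_mid[:, None] - g_mid[None, :]).argmin(axis=1)
    element_to_gene = {
        f"EL{e}": [f"G{nearest[e]}"]
        for e in range(cfg.n_elements)
        if abs(el_mid[e] - g_mid[nearest[e]]) <= 1_000_000
    }

    # --- SNP table ----------------------------------------------------------
    rows = []
    snp_to_element: dict[str, str] = {}
    snp_to_gene: dict[str, str] = {}
    for j in range(cfg.n_noncoding_snps):
        e = j % cfg.n_elements
        pos = int(el_starts[e]) + 1 + (j // cfg.n_elements)  # inside [start, end)
        sid = f"chr1:{pos}"
        rows.append((sid, "chr1", pos, "A", "G", "noncoding", False))
        snp_to_element[sid] = f"EL{e}"
        if f"EL{e}" in element_to_gene:
            snp_to_gene[sid] = element_to_gene[f"EL{e}"][0]
    used = {pos for _, _, pos, *_ in rows}
    for j in range(cfg.n_coding_snps):
        g = j % cfg.n_genes
        pos = int(gene_starts[g]) + 1 + (j // cfg.n_genes)
        while pos in used:  # avoid collisions with element-hosted SNPs
            pos += 1
        used.add(pos)
        sid = f"chr1:{pos}"
        rows.append((sid, "chr1", pos, "C", "T", "coding", False))
        snp_to_gene[sid] = f"G{g}"
    snps = SnpTable(pd.DataFrame(rows, columns=list(SnpTable.REQUIRED)))
    snp_ids = snps.snp_ids
    p = len(snp_ids)
    noncoding_ids = snps.ids_in_category("noncoding")
    coding_ids = snps.ids_in_category("coding")

    # --- genotypes ----------------------------------------------------------
    maf = rng.uniform(*cfg.maf_range, size=p)
    codes = _simulate_genotypes(cfg, maf, rng)

    # --- causal structure ---------------------------------------------------
    occupied = sorted({int(snp_to_element[s][2:]) for s in noncoding_ids})
    if cfg.n_causal_elements > len(occupied):
        raise ValueError(
            f"cannot place {cfg.n_causal_elements} causal elements: only "
            f"{len(occupied)} elements host a SNP"
        )
    causal_elements = sorted(
        rng.choice(occupied, cfg.n_causal_elements, replace=False)
    )
    causal_nc = []
    for e in causal_elements:
        members = [s for s in noncoding_ids if snp_to_element[s] == f"EL{e}"]
        causal_nc.append(members[rng.integers(len(members))])
    causal_cod = [
        coding_ids[k]
        for k in sorted(rng.choice(cfg.n_coding_snps, cfg.n_causal_coding, replace=False))
    ]
    causal_ids = causal_nc + causal_cod
    causal_set = set(causal_ids)
    causal_genes = sorted({snp_to_gene[s] for s in causal_ids if s in snp_to_gene})

    # --- impact scores: large allelic deltas only at causal SNPs ------------
    def allele_scores(ids: list[str]) -> pd.DataFrame:
        ref = rng.uniform(0.2, 0.6, size=len(ids))
        delta = np.where(
            [s in causal_set for s in ids],
            rng.uniform(0.25, 0.45, size=len(ids)) * rng.choice([-1, 1], size=len(ids)),
            rng.normal(0.0, 0.01, size=len(ids)),
        )
        alt = np.clip(ref + delta, 0.0, 1.0)
        return pd.DataFrame({"ref_score": ref, "alt_score": alt}, index=pd.Index(ids))

    impacts = ImpactScores(
        noncoding_access=allele_scores(noncoding_ids),
        coding_mfe=allele_scores(coding_ids),
        peak_threshold=0.147,
    )

    # --- functional annotation matrices -------------------------------------
    n_causal_terms = max(1, cfg.n_terms // 10)
    causal_terms = [f"T{t}" for t in range(n_causal_terms)]
    causal_metaterms = ["MT0"]
    rank = min(5, cfg.n_terms, cfg.n_genes)
    scores = (
        rng.normal(0, 1, (cfg.n_genes, rank)) @ rng.normal(0, 0.4, (rank, cfg.n_terms))
        + rng.normal(0, 0.05, (cfg.n_genes, cfg.n_terms))
    )
    gene_term = pd.DataFrame(
        scores,
        index=pd.Index([f"G{g}" for g in range(cfg.n_genes)]),
        columns=[f"T{t}" for t in range(cfg.n_terms)],
    )
    gene_term.loc[causal_genes, causal_terms] += 2.0
    # each term loads on a single metaterm (factorization modules are near
    # disjoint); causal terms form the signature of MT0
    term_meta = pd.DataFrame(
        0.0,
        index=gene_term.columns,
        columns=[f"MT{m}" for m in range(cfg.n_metaterms)],
    )
    other_terms = [t for t in gene_term.columns if t not in causal_terms]
    assignment = rng.integers(1, cfg.n_metaterms, size=len(other_terms)) if (
        cfg.n_metaterms > 1
    ) else np.zeros(len(other_terms), dtype=int)
    for t, m in zip(other_terms, assignment):
        term_meta.at[t, f"MT{m}"] = rng.normal(0, 0.5)
    for t in causal_terms:
        term_meta.at[t, "MT0"] = 2.0 + rng.normal(0, 0.2)

    gene_index = pd.Index([f"G{g}" for g in range(cfg.n_genes)])
    conserved = pd.Series(rng.random(cfg.n_genes) < 0.2, index=gene_index)
    conserved[causal_genes] = True
    signature = pd.Series(rng.random(cfg.n_genes) < 0.1, index=gene_index)
    signature[causal_genes] = True
    # causal coding variants are modelled as nonsynonymous changes
    frame = snps.frame
    frame.loc[frame["snp_id"].isin(causal_cod), "nonsynonymous_flag"] = True
    extra_ns = rng.random(len(frame)) < 0.3
    frame.loc[(frame["category"] == "coding") & extra_ns, "nonsynonymous_flag"] = True

    bundle = AnnotationBundle(
        element_intervals=elements,
        snp_to_element=snp_to_element,
        gene_intervals=genes,
        element_to_gene=element_to_gene,
        snp_to_gene=snp_to_gene,
        gene_term_scores=gene_term,
        term_metaterm_weights=term_meta,
        conserved_gene_flags=conserved,
        signature_gene_flags=signature,
    )
    bundle.validate(snps)
    impacts.validate_coverage(snps)

    # --- additive effects: BayesR-style mixture scaled by impact delta ------
    col = {s: j for j, s in enumerate(snp_ids)}
    effects = pd.Series(0.0, index=pd.Index(causal_ids))
    h2 = cfg.heritability_target
    if h2 > 0:
        comp = rng.choice([1, 2, 3], size=len(causal_ids), p=cfg.mixture_probs)
        raw = rng.standard_normal(len(causal_ids)) * np.sqrt(
            np.array(MIXTURE_SCALES)[comp]
        )
        deltas = np.array([impacts.delta(s) for s in causal_ids])
        effects[:] = raw * deltas / 0.35  # proportional to allelic impact

    genetic = codes[:, [col[s] for s in causal_ids]] @ effects.to_numpy()

    interactions: list[tuple[str, str, float]] = []
    if h2 > 0 and cfg.interaction_fraction > 0 and len(causal_ids) > 1:
        mt_pairs = [
            (a, b)
            for i, a in enumerate(causal_ids)
            for b in causal_ids[i + 1 :]
            if snp_to_gene.get(a) in causal_genes and snp_to_gene.get(b) in causal_genes
        ]
        n_pick = int(round(cfg.interaction_fraction * len(mt_pairs)))
        if n_pick:
            picks = rng.choice(len(mt_pairs), n_pick, replace=False)
            scale = np.abs(effects.to_numpy()).mean()
            for k in picks:
                a, b = mt_pairs[k]
                w = rng.normal(0, scale)
                za = codes[:, col[a]] - codes[:, col[a]].mean()
                zb = codes[:, col[b]] - codes[:, col[b]].mean()
                genetic = genetic + w * za * zb
                interactions.append((a, b, float(w)))

    # --- environmental noise scaled to the target heritability --------------
    var_g = float(np.var(genetic))
    if h2 > 0 and var_g > 0:
        noise = rng.standard_normal(cfg.n_samples) * np.sqrt(var_g * (1 - h2) / h2)
    else:
        noise = rng.standard_normal(cfg.n_samples)
    y = genetic + noise
    var_e = float(np.var(noise))
    realized = var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0

    samples = [f"S{i}" for i in range(cfg.n_samples)]
    gm = GenotypeMatrix(samples, snps, codes)
    ph = PhenotypeVector("trait", y)
    truth = SimTruth(
        causal_snp_ids=causal_ids,
        effects=effects,
        causal_gene_ids=causal_genes,
        causal_term_ids=causal_terms,
        causal_metaterm_ids=causal_metaterms,
        realized_heritability=realized,
        interactions=interactions,
    )
    return gm, bundle, impacts, ph, truth


def write_cohort(out_dir, gm, bundle, impacts, phenotype, truth) -> None:
    """Write every cohort component in the package's on-disk formats."""
    from pathlib import Path

    from . import io as _io

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    _io.write_genotypes(gm, d / "genotypes.tsv")
    _io.write_snp_table(gm.snps, d / "snps.tsv")
    _io.write_phenotype(phenotype, gm.samples, d / "phenotype.tsv")
    _io.write_annotation_bundle(bundle, d / "bundle")
    _io.write_impact_scores(impacts, d / "bundle")
    pd.DataFrame(
        {
            "snp_id": truth.causal_snp_ids,
            "effect": truth.effects.to_numpy(),
        }
    ).to_csv(d / "truth.tsv", sep="\t", index=False)
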