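import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from annogs.interpret import (
    NodeRankLists,
    aggregate_layer,
    available_layers,
    backward_trace,
    extract_node_weights,
    prioritize_cis_snps,
    rho_score,
)
from annogs.io import GenotypeMatrix, ImpactScores, PhenotypeVector, SnpTable
from annogs.network import NetworkSpec, build_network
from annogs.simulate import SimConfig, simulate_cohort


class TestRhoScore:
    def test_single_uniform_rank(self):
        rho, p = rho_score([0.5])
        assert rho == pytest.approx(0.5) and p == pytest.approx(0.5)

    def test_two_rank_closed_form(self):
        # betaScores (1 - 0.9^2, 0.9^2) = (0.19, 0.81); rho = 0.19, p = 0.38
        rho, p = rho_score([0.1, 0.9])
        assert rho == pytest.approx(0.19)
        assert p == pytest.approx(0.38)

    def test_vanishing_ranks(self):
        rho, p = rho_score([1e-9, 1e-9, 1e-9])
        assert rho < 1e-8 and p < 1e-7

    def test_rank_domain_checks(self):
        with pytest.raises(ValueError):
            rho_score([0.0, 0.5])
        with pytest.raises(ValueError):
            rho_score([0.5, 1.2])

    def test_matches_order_statistic_simulation(self):
        # oracle: P(Beta(k, m-k+1) <= r) is the chance the k-th smallest of m
        # uniforms falls below r
        rng = np.random.default_rng(0)
        m = 3
        u = np.sort(rng.random((200_000, m)), axis=1)
        ranks = [0.2, 0.55, 0.7]
        r_sorted = np.sort(ranks)
        sim_scores = [(u[:, k] <= r_sorted[k]).mean() for k in range(m)]
        exact = beta_dist.cdf(r_sorted, np.arange(1, m + 1), np.arange(m, 0, -1))
        for s, e in zip(sim_scores, exact):
            assert abs(s - e) < 3 * np.sqrt(e * (1 - e) / 200_000) + 1e-4
        rho, _ = rho_score(ranks)
        assert rho == pytest.approx(min(exact))

    def test_enumeration_toy(self):
        # m=3 lists over N=4 items: ranks are multiples of 1/4
        ranks = [1 / 4, 2 / 4, 2 / 4]
        rho, p = rho_score(ranks)
        # manual order-statistic evaluation
        exp = min(
            1 - (1 - 0.25) ** 3,
            beta_dist.cdf(0.5, 2, 2),
            0.5**3,
        )
        assert rho == pytest.approx(exp)
        assert p == pytest.approx(min(1.0, 3 * exp))


class TestAggregateLayer:
    def test_dominant_node_has_smallest_p(self):
        rng = np.random.default_rng(1)
        N, m = 100, 5
        ranks = np.column_stack(
            [rng.permutation(N) + 1 for _ in range(m)]
        ).astype(float) / N
        ranks[0, :] = 1.0 / N  # node 0 ranked first in every replicate
        lists = NodeRankLists("gene", [f"n{i}" for i in range(N)], ranks)
        out = aggregate_layer(lists, alpha=0.01)
        assert out.index[0] == "n0"
        assert out["adjusted_p"].iloc[0] == out["adjusted_p"].min()
        assert bool(out["significant"].iloc[0])

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        N, m, reps, alpha = 60, 5, 300, 0.05
        any_flag = 0
        for _ in range(reps):
            ranks = np.column_stack(
                [rng.permutation(N) + 1 for _ in range(m)]
            ).astype(float) / N
            lists = NodeRankLists("gene", [str(i) for i in range(N)], ranks)
            out = aggregate_layer(lists, alpha=alpha)
            if out["significant"].any():
                any_flag += 1
        # under the full null, FDR equals the family-wise rejection rate
        assert any_flag / reps <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)


@pytest.fixture(scope="module")
def traced_cohort():
    cfg = SimConfig(
        n_samples=300,
        n_noncoding_snps=150,
        n_coding_snps=30,
        n_elements=30,
        n_genes=12,
        n_terms=12,
        n_metaterms=10,
        n_causal_elements=10,
        n_causal_coding=4,
        heritability_target=0.6,
        seed=21,
    )
    return simulate_cohort(cfg)


def train_replicates(cohort, n_rep=5, seed=0, level=4, steps=60):
    gm, bundle, impacts, ph, _ = cohort
    rng = np.random.default_rng(seed)
    nets = []
    n = gm.n_samples
    for rep in range(n_rep):
        sub = rng.choice(n, int(0.8 * n), replace=False)
        gm_s = GenotypeMatrix([gm.samples[i] for i in sub], gm.snps, gm.codes[sub])
        ph_s = PhenotypeVector(ph.trait, ph.values[sub])
        spec = NetworkSpec(
            annotation_level=level, base_unit=16, unit_ratio=(3, 1, 1, 1, 1, 1),
            learning_rate=0.1, dropout_rate=0.0, momentum=0.9,
        )
        net = build_network(bundle, impacts, spec, gm_s, seed=seed * 100 + rep)
        net.train(gm_s, ph_s, steps=steps, seed=seed * 100 + rep)
        nets.append(net)
    return nets


class TestNodeWeights:
    def test_single_node_layer_rank_one(self, traced_cohort):
        nets = train_replicates(traced_cohort, n_rep=2, seed=3)
        gm, bundle, *_ = traced_cohort
        lists = extract_node_weights(nets, "metaterm", bundle)
        assert lists.ranks.shape == (10, 2)
        for col in lists.ranks.T:  # each replicate: a permutation / N
            assert sorted(col) == pytest.approx(list(np.arange(1, 11) / 10))

    def test_zero_outgoing_weight_node_ranks_last(self, traced_cohort):
        nets = train_replicates(traced_cohort, n_rep=1, seed=4)
        gm, bundle, *_ = traced_cohort
        net = nets[0]
        base = net.spec.internal_widths[1]
        # every other metaterm row gets some weight; MT3's is zeroed out
        net.params[2]["W"][base : base + 10, 0] += 0.05
        net.params[2]["W"][base + 3, :] = 0.0
        lists = extract_node_weights([net], "metaterm", bundle)
        idx = lists.node_ids.index("MT3")
        assert lists.ranks[idx, 0] == pytest.approx(1.0)

    def test_mismatched_specs_rejected(self, traced_cohort):
        nets = train_replicates(traced_cohort, n_rep=1, seed=5)
        other = train_replicates(traced_cohort, n_rep=1, seed=5, level=1)
        with pytest.raises(ValueError, match="spec"):
            extract_node_weights([nets[0], other[0]], "noncoding_snp")

    def test_level1_exposes_only_snp_layers(self, traced_cohort):
        nets = train_replicates(traced_cohort, n_rep=1, seed=6, level=1, steps=5)
        assert available_layers(nets[0]) == ["noncoding_snp", "coding_snp"]


class TestBackwardTrace:
    def test_causal_metaterm_recovered(self, traced_cohort):
        gm, bundle, impacts, ph, truth = traced_cohort
        hits_top = 0
        for run in range(5):
            nets = train_replicates(traced_cohort, n_rep=5, seed=10 + run)
            traced = backward_trace(nets, bundle, alpha_node=0.01)
            mt = traced["metaterm"]
            if mt.index[0] in truth.causal_metaterm_ids:
                hits_top += 1
        assert hits_top >= 3

    def test_permuted_phenotype_yields_null_counts(self, traced_cohort):
        # each replicate breaks the genotype-phenotype link with its own
        # permutation, so across-replicate ranks are exchangeable
        gm, bundle, impacts, ph, _ = traced_cohort
        rng = np.random.default_rng(7)
        nets = []
        for rep in range(5):
            ph_perm = PhenotypeVector(ph.trait, rng.permutation(ph.values))
            cohort_perm = (gm, bundle, impacts, ph_perm, None)
            nets += train_replicates(cohort_perm, n_rep=1, seed=80 + rep)
        traced = backward_trace(nets, bundle, alpha_node=0.01)
        n_sig = sum(int(frame["significant"].sum()) for frame in traced.values())
        n_nodes = sum(len(frame) for frame in traced.values())
        # replicates share the genotype matrix, which leaves some residual
        # rank correlation under the null; the flagged fraction stays far
        # below any signal-bearing layer's hit rate
        assert n_sig <= max(4, 0.04 * n_nodes)


class TestCisPrioritization:
    def make_inputs(self):
        gene_start = 2_000_000
        genes = pd.DataFrame(
            [("chr1", gene_start, gene_start + 20_000, "G")],
            columns=["chrom", "start", "end", "gene_id"],
        )
        snps = []
        # exactly 1 Mb upstream of the gene boundary (boundary inclusive)
        snps.append(("at_window", "chr1", gene_start - 1_000_000 + 1))
        snps.append(("below_peak", "chr1", gene_start - 500))
        snps.append(("outside", "chr1", gene_start - 1_000_001 + 1 - 1))
        snps.append(("weak_p", "chr1", gene_start - 600))
        snps.append(("second", "chr1", gene_start + 25_000))
        table = SnpTable(
            pd.DataFrame(
                [(s, c, p, "A", "G", "noncoding", False) for s, c, p in snps],
                columns=list(SnpTable.REQUIRED),
            )
        )
        access = pd.DataFrame(
            {
                "ref_score": [0.5, 0.117, 0.5, 0.5, 0.3],
                "alt_score": [0.2, 0.106, 0.2, 0.2, 0.168],
            },
            index=pd.Index([s for s, _, _ in snps]),
        )
        impacts = ImpactScores(access, pd.DataFrame(columns=["ref_score", "alt_score"]),
                               peak_threshold=0.147)
        sig = pd.DataFrame(
            {"adjusted_p": [0.001, 0.001, 0.001, 0.2, 0.01]},
            index=pd.Index([s for s, _, _ in snps]),
        )
        return table, impacts, sig, genes

    def test_filters_and_ranking(self):
        table, impacts, sig, genes = self.make_inputs()
        out = prioritize_cis_snps(["G"], table, impacts, sig, genes)
        assert out["snp_id"].tolist() == ["at_window", "second"]
        assert out.loc[0, "distance"] == 1_000_000
        # allele scores 0.117 / 0.106 both below the 0.147 peak threshold:
        # excluded regardless of significance
        assert "below_peak" not in set(out["snp_id"])
        assert "outside" not in set(out["snp_id"])
        assert "weak_p" not in set(out["snp_id"])

    def test_causal_cis_snp_outranks_neighbours(self, traced_cohort):
        gm, bundle, impacts, ph, truth = traced_cohort
        wins = 0
        for run in range(5):
            nets = train_replicates(traced_cohort, n_rep=5, seed=40 + run)
            traced = backward_trace(nets, bundle, alpha_node=0.01)
            snp_frame = traced["noncoding_snp"]
            causal_nc = [s for s in truth.causal_snp_ids if s in snp_frame.index]
            med_causal = snp_frame.loc[causal_nc, "adjusted_p"].median()
            others = snp_frame.index.difference(causal_nc)
            med_other = snp_frame.loc[others, "adjusted_p"].median()
            if med_causal < med_other:
                wins += 1
        assert wins >= 3
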