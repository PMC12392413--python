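"""Backward tracing: attributing trained network weights to biology.

For each cross-validation replicate, every node of a biological layer
(metaterm, term, gene, element, SNP, RNA-structure) is scored by the sum of
absolute outgoing weights and ranked; the m normalized rank positions of a
node are then combined with a beta order-statistic score

    rho = min_k P(Beta(k, m-k+1) <= r_(k))

(the robust rank aggregation statistic), Bonferroni-corrected within the
node (x m) and Benjamini-Hochberg-corrected across the nodes of a layer.
Significant genes seed a cis-window scan that nominates candidate
regulatory SNPs, filtered by the open-chromatin peak threshold on their
allele-level accessibility scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from statsmodels.stats.multitest import multipletests

from .io import AnnotationBundle, ImpactScores, SnpTable
from .network import AnnotationNetwork

__all__ = [
    "NodeRankLists",
    "LAYER_NAMES",
    "available_layers",
    "extract_node_weights",
    "rho_score",
    "aggregate_layer",
    "backward_trace",
    "prioritize_cis_snps",
]

LAYER_NAMES = (
    "metaterm",
    "term",
    "gene",
    "element",
    "noncoding_snp",
    "rna_structure",
    "coding_snp",
)


@dataclass
class NodeRankLists:
    layer: str
    node_ids: list[str]
    ranks: np.ndarray  # (n_nodes, m replicates), normalized in (0, 1]


def available_layers(net: AnnotationNetwork) -> list[str]:
    """Biological layers that exist at the network's annotation level."""
    level = net.spec.annotation_level
    layers = ["noncoding_snp", "coding_snp"]
    if level >= 2:
        layers += ["rna_structure", "element"]
    if level >= 3:
        layers += ["gene", "term"]
    if level >= 4:
        layers.append("metaterm")
    return [l for l in layers if _entity_rows(net, l)[0]]


def _entity_rows(net: AnnotationNetwork, layer: str):
    """(node ids, list of (affine index, row indices) per node) for a layer."""
    p = len(net.snp_ids)
    noncoding = net._noncoding
    widths = net.spec.internal_widths
    if layer in ("noncoding_snp", "coding_snp", "rna_structure"):
        sel = noncoding if layer == "noncoding_snp" else ~noncoding
        ids = [s for s, keep in zip(net.snp_ids, sel) if keep]
        rows = []
        for j in np.flatnonzero(sel):
            r = [] if layer == "rna_structure" else [(0, j)]
            if net._inject.get(0, 0) and layer in ("noncoding_snp", "rna_structure"):
                r.append((0, p + j))
            rows.append(r)
        if layer == "rna_structure" and not net._inject.get(0, 0):
            return [], []
        return ids, rows
    if layer == "element":
        groups: dict[str, list] = {}
        for k, (kind, ent) in enumerate(net.h1_entities):
            if kind == "element":
                groups.setdefault(ent, []).append((1, k))
        return list(groups), [groups[e] for e in groups]
    if layer == "gene":
        groups = {}
        for k, (kind, ent) in enumerate(net.h2_entities):
            if kind == "gene":
                groups.setdefault(ent, []).append((2, k))
        return list(groups), [groups[g] for g in groups]
    if layer == "term":
        if not net._inject.get(1, 0):
            return [], []
        base = widths[0]
        # term injection rows sit after the H1 block in the second affine
        ids = [f"T{i}" for i in range(net.n_terms)]
        return ids, [[(1, base + i)] for i in range(net.n_terms)]
    if layer == "metaterm":
        if not net._inject.get(2, 0):
            return [], []
        base = widths[1]
        ids = [f"MT{i}" for i in range(net.n_meta)]
        return ids, [[(2, base + i)] for i in range(net.n_meta)]
    raise ValueError(f"unknown layer {layer!r}")


def _term_ids(net: AnnotationNetwork, bundle: AnnotationBundle | None, layer: str, ids):
    if bundle is None:
        return ids
    if layer == "term" and bundle.terms:
        return list(bundle.terms)
    if layer == "metaterm" and bundle.metaterms:
        return list(bundle.metaterms)
    return ids


def extract_node_weights(
    models: list[AnnotationNetwork],
    layer: str,
    bundle: AnnotationBundle | None = None,
    statistic: str = "weight",
) -> NodeRankLists:
    """Rank every node of ``layer`` by summed |outgoing weight|, per model.

    All models must share the same architecture (SNP set, widths, level);
    ranks are normalized to (0, 1] by the node count.  The default
    ``weight`` statistic is the plain sum of absolute outgoing weights
    (annotation-feature weights start at zero, so trained magnitudes reflect
    learned relevance); ``scaled`` additionally multiplies by the
    training-set standard deviation of the node's value, measuring the
    contribution on the standardized-input scale.
    """
    if not models:
        raise ValueError("need at least one trained model")
    if statistic not in ("weight", "scaled"):
        raise ValueError(f"unknown statistic {statistic!r}")
    ref = models[0]
    for m in models[1:]:
        if m.snp_ids != ref.snp_ids or m.spec.internal_widths != ref.spec.internal_widths \
                or m.spec.annotation_level != ref.spec.annotation_level:
            raise ValueError("models do not share a network spec")
    ids, rows = _entity_rows(ref, layer)
    ids = _term_ids(ref, bundle, layer, ids)
    if not ids:
        raise ValueError(f"layer {layer!r} has no nodes at this annotation level")
    N = len(ids)
    ranks = np.zeros((N, len(models)))
    for mi, net in enumerate(models):
        if statistic == "scaled":
            scales = {aff: net.input_scales(aff)
                      for aff in (0, 1, 2) if aff < len(net.params)}
        else:
            scales = {aff: np.ones(net._dims[aff][0])
                      for aff in (0, 1, 2) if aff < len(net.params)}
        score = np.zeros(N)
        for ni, row_list in enumerate(rows):
            for aff, r in row_list:
                score[ni] += float(
                    np.abs(net.params[aff]["W"][r, :]).sum() * scales[aff][r]
                )
        order = np.argsort(-score, kind="stable")
        rank_of = np.empty(N, dtype=float)
        rank_of[order] = np.arange(1, N + 1)
        ranks[:, mi] = rank_of / N
    return NodeRankLists(layer, list(ids), ranks)


def rho_score(normalized_ranks) -> tuple[float, float]:
    """Beta order-statistic aggregation of one node's ranks across lists.

    Sorting the m normalized ranks ascending, the k-th score is
    ``P(Beta(k, m-k+1) <= r_(k))``; rho is their minimum and the corrected
    p value is ``min(1, rho * m)`` (Bonferroni over the m order statistics).
    """
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    m = r.size
    if m == 0:
        raise ValueError("need at least one rank")
    if (r <= 0).any() or (r > 1).any():
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = np.arange(1, m + 1)
    scores = beta_dist.cdf(r, k, m - k + 1)
    rho = float(scores.min())
    return rho, float(min(1.0, rho * m))


def aggregate_layer(rank_lists: NodeRankLists, alpha: float = 0.01) -> pd.DataFrame:
    """Per-node rho scores with Benjamini-Hochberg correction across the
    layer; returns a frame indexed by node id, sorted by adjusted p."""
    rhos, pvals = zip(*(rho_score(row) for row in rank_lists.ranks))
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "rho_score": rhos,
            "p_corrected": pvals,
            "adjusted_p": adj,
            "significant": adj < alpha,
        },
        index=pd.Index(rank_lists.node_ids, name="node"),
    )
    return out.sort_values("adjusted_p", kind="stable")


def backward_trace(
    models: list[AnnotationNetwork],
    bundle: AnnotationBundle,
    alpha_node: float = 0.01,
    statistic: str = "weight",
) -> dict[str, pd.DataFrame]:
    """Aggregate every biological layer across CV replicates.

    Returns a mapping layer -> significance frame; significant nodes map
    one-to-one onto bundle entities (genes, elements, terms, metaterms or
    SNPs), giving the metaterm -> term -> gene -> element/SNP causal chain
    with each link's adjusted p value.
    """
    out = {}
    for layer in available_layers(models[0]):
        lists = extract_node_weights(models, layer, bundle, statistic)
        out[layer] = aggregate_layer(lists, alpha_node)
    return out


def prioritize_cis_snps(
    significant_genes: list[str],
    snps: SnpTable,
    impacts: ImpactScores,
    snp_significance: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    window: int = 1_000_000,
    alpha_snp: float = 0.05,
) -> pd.DataFrame:
    """Candidate cis-regulatory SNPs for the significant genes.

    A noncoding SNP qualifies when it (i) lies within ``window`` bp of a
    significant gene (boundary inclusive), (ii) is itself significant at
    ``alpha_snp`` in the SNP layer, and (iii) has at least one allele whose
    accessibility score reaches the open-chromatin peak threshold.  Ranked
    by adjusted p.
    """
    genes = gene_intervals[gene_intervals["gene_id"].isin(significant_genes)]
    rows = []
    frame = snps.frame
    nc = frame[frame["category"] == "noncoding"]
    acc = impacts.noncoding_access
    for snp in nc.itertuples(index=False):
        if snp.snp_id not in snp_significance.index:
            continue
        adj = float(snp_significance.at[snp.snp_id, "adjusted_p"])
        if not adj < alpha_snp:
            continue
        if snp.snp_id not in acc.index:
            continue
        ref_s = float(acc.at[snp.snp_id, "ref_score"])
        alt_s = float(acc.at[snp.snp_id, "alt_score"])
        pos0 = snp.pos - 1
        for g in genes.itertuples(index=False):
            if g.chrom != snp.chrom:
                continue
            if g.start <= pos0 < g.end:
                dist = 0
            elif pos0 < g.start:
                dist = g.start - pos0
            else:
                dist = pos0 - (g.end - 1)
            if dist <= window:
                in_peak = max(ref_s, alt_s) >= impacts.peak_threshold
                if in_peak:
                    rows.append(
                        (snp.snp_id, g.gene_id, int(dist), adj, ref_s, alt_s)
                    )
                break
    out = pd.DataFrame(
        rows,
        columns=["snp_id", "gene_id", "distance", "adjusted_p", "ref_score", "alt_score"],
    )
    return out.sort_values("adjusted_p", kind="stable").reset_index(drop=True)
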