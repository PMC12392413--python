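"""Random hyperparameter search with a per-level voting selector.

Candidates are drawn uniformly without replacement from the grid product and
each is evaluated by 2-fold cross-validation at every annotation level (1-4).
For each hyperparameter dimension, the best value is selected per
(level, statistic) pair where the statistic is the mean or median PCC over
all candidates sharing a value — 4 levels x 2 statistics = 8 selections
counted as votes.  The modal value wins; vote ties are broken by the higher
overall average PCC, and exact PCC ties deterministically by grid order.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import make_folds, pcc
from .io import AnnotationBundle, GenotypeMatrix, ImpactScores, PhenotypeVector
from .network import NetworkSpec, build_network

__all__ = [
    "DEFAULT_GRID",
    "VoteResult",
    "sample_candidates",
    "evaluate_candidates",
    "select_by_vote",
    "tally_votes",
    "break_tie",
]

logger = logging.getLogger(__name__)

# values named in the search space: learning rates span five decades and the
# canonical momentum pair is {0.9, 0.95}
DEFAULT_GRID: dict[str, list] = {
    "learning_rate": [0.1, 0.01, 0.001, 0.0001, 0.00001],
    "reg_norm": ["L1", "L2"],
    "reg_rate": [0.1, 0.01, 0.001],
    "momentum": [0.9, 0.95],
    "bn_momentum": [0.9, 0.95, 0.99],
    "dropout_rate": [0.0, 0.1, 0.3],
    "base_unit": [55, 110],
    "unit_ratio": [(1, 2, 4, 5, 6, 7), (1, 1, 2, 2, 4, 4)],
}


@dataclass
class VoteResult:
    """Per-dimension voting outcome over (level, statistic) selections."""

    selections: dict[str, dict[tuple[int, str], object]]
    vote_counts: dict[str, dict[object, int]]
    winners: dict[str, object]
    tie_break_used: dict[str, bool]
    tie_break_pccs: dict[str, dict[object, float]] = field(default_factory=dict)

    def best_candidate(self) -> dict:
        return dict(self.winners)


def sample_candidates(grid: dict[str, list], count: int = 500, seed: int = 0) -> list[dict]:
    """Uniform draws without replacement from the grid's cartesian product.

    When the product holds fewer than ``count`` combinations the whole
    product is returned.  Identical seeds yield identical candidate lists.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    dims = list(grid)
    if any(len(grid[d]) == 0 for d in dims):
        raise ValueError("every grid dimension must be non-empty")
    sizes = [len(grid[d]) for d in dims]
    total = math.prod(sizes)
    rng = np.random.default_rng(seed)
    if total <= count:
        combos = list(itertools.product(*(grid[d] for d in dims)))
    else:
        chosen: list[int] = []
        seen: set[int] = set()
        while len(chosen) < count:
            i = int(rng.integers(total))
            if i not in seen:
                seen.add(i)
                chosen.append(i)
        combos = []
        for flat in chosen:
            idx = np.unravel_index(flat, sizes)
            combos.append(tuple(grid[d][k] for d, k in zip(dims, idx)))
    return [dict(zip(dims, combo)) for combo in combos]


def evaluate_candidates(
    candidates: list[dict],
    genotypes: GenotypeMatrix,
    bundle: AnnotationBundle,
    impacts: ImpactScores,
    phenotypes: PhenotypeVector,
    levels: tuple[int, ...] = (1, 2, 3, 4),
    folds: int = 2,
    seed: int = 0,
    steps: int = 60,
) -> pd.DataFrame:
    """Fold-averaged test-set PCC for every candidate at every level.

    All levels share the same fold plan and candidate pool so votes are
    comparable.  A failed or degenerate (zero-variance) training run is
    recorded as NaN and excluded from vote aggregation.
    """
    n = genotypes.n_samples
    plan = make_folds(n, folds, seed)
    y = np.asarray(phenotypes.values, dtype=float)
    table = pd.DataFrame(index=range(len(candidates)), columns=list(levels), dtype=float)
    for ci, cand in enumerate(candidates):
        for level in levels:
            spec = NetworkSpec(annotation_level=level, **cand)
            fold_pccs = []
            try:
                for f in range(folds):
                    tr, te = plan.train_indices(f), plan.test_indices(f)
                    gm_tr = GenotypeMatrix(
                        [genotypes.samples[i] for i in tr], genotypes.snps,
                        genotypes.codes[tr],
                    )
                    gm_te = GenotypeMatrix(
                        [genotypes.samples[i] for i in te], genotypes.snps,
                        genotypes.codes[te],
                    )
                    net = build_network(bundle, impacts, spec, gm_tr, seed=seed)
                    net.train(gm_tr, PhenotypeVector(phenotypes.trait, y[tr]),
                              steps=steps, seed=seed)
                    pred = net.predict(gm_te).values
                    fold_pccs.append(pcc(y[te], pred))
                value = float(np.mean(fold_pccs))
            except (RuntimeError, FloatingPointError, ValueError) as exc:
                logger.warning("candidate %d level %d failed: %s", ci, level, exc)
                value = float("nan")
            table.loc[ci, level] = value
    return table


def tally_votes(selections: list, values: list) -> dict:
    """Count how often each grid value was selected across the 8
    (level, statistic) slots."""
    counts = {v: 0 for v in values}
    for sel in selections:
        if sel is not None:
            counts[sel] = counts.get(sel, 0) + 1
    return counts


def break_tie(tied_values: list, avg_pcc: dict, grid_values: list):
    """Higher overall average PCC wins; an exact PCC tie falls back to the
    first-listed grid value."""
    best = max(
        tied_values,
        key=lambda v: (avg_pcc.get(v, float("-inf")), -grid_values.index(v)),
    )
    return best


def select_by_vote(
    pcc_table: pd.DataFrame,
    candidates: list[dict],
    grid: dict[str, list] | None = None,
) -> VoteResult:
    """Vote over per-(level, statistic) best values for every dimension."""
    if pcc_table.empty:
        raise ValueError("empty PCC table")
    levels = list(pcc_table.columns)
    dims = list(candidates[0])
    grid = grid or {
        d: sorted({c[d] for c in candidates}, key=lambda v: str(v)) for d in dims
    }
    frame = pd.DataFrame(candidates)
    frame["__row"] = range(len(candidates))

    selections: dict[str, dict] = {}
    counts: dict[str, dict] = {}
    winners: dict[str, object] = {}
    tie_used: dict[str, bool] = {}
    tie_pccs: dict[str, dict] = {}
    for dim in dims:
        sel: dict[tuple[int, str], object] = {}
        col = frame[dim].map(lambda v: tuple(v) if isinstance(v, list) else v)
        marg_all: dict[object, float] = {}
        for value in grid[dim]:
            key = tuple(value) if isinstance(value, list) else value
            rows = frame.loc[col == key, "__row"]
            block = pcc_table.loc[rows, levels].to_numpy(dtype=float)
            marg_all[value] = float(np.nanmean(block)) if rows.size and not np.isnan(
                block
            ).all() else float("nan")
        for level in levels:
            for stat_name, stat in (("mean", np.nanmean), ("median", np.nanmedian)):
                best_val, best_pcc = None, float("-inf")
                for value in grid[dim]:
                    key = tuple(value) if isinstance(value, list) else value
                    rows = frame.loc[col == key, "__row"]
                    if not rows.size:
                        continue
                    vals = pcc_table.loc[rows, level].to_numpy(dtype=float)
                    if np.isnan(vals).all():
                        continue
                    agg = float(stat(vals))
                    if agg > best_pcc:
                        best_pcc, best_val = agg, value
                sel[(level, stat_name)] = best_val
        tally = tally_votes(list(sel.values()), grid[dim])
        top = max(tally.values())
        tied = [v for v in grid[dim] if tally[v] == top]
        if len(tied) > 1:
            winners[dim] = break_tie(tied, marg_all, grid[dim])
            tie_used[dim] = True
            tie_pccs[dim] = {v: marg_all[v] for v in tied}
            logger.info("dimension %s tie between %s broken by average PCC", dim, tied)
        else:
            winners[dim] = tied[0]
            tie_used[dim] = False
        selections[dim] = sel
        counts[dim] = tally
    return VoteResult(selections, counts, winners, tie_used, tie_pccs)
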