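"""Cross-validation harness and evaluation statistics.

Implements the Pearson-correlation accuracy in its two flavours (test folds
pooled before the correlation, or one correlation per fold), the relative
efficiency of top-k selection, the fold-paired t test, and the heritability
explained by a SNP subset (REML on the subset-restricted relationship
matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, PhenotypeVector
from .linear import fit_gblup

__all__ = [
    "CvPlan",
    "CvResult",
    "make_folds",
    "pcc",
    "relative_efficiency",
    "re_curve",
    "paired_t",
    "heritability_of_subset",
    "cross_validate",
]


@dataclass
class CvPlan:
    n: int
    k: int
    fold_id: np.ndarray  # fold index per sample
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


@dataclass
class CvResult:
    plan: CvPlan
    observed: np.ndarray
    predicted: np.ndarray  # every sample predicted exactly once
    model: str = ""
    per_fold_pcc: list[float] = field(default_factory=list)
    pooled_pcc: float = float("nan")


def make_folds(n: int, k: int, seed: int = 0) -> CvPlan:
    """Seeded random partition into k folds with sizes differing by <= 1."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    fold_id = np.array([i % k for i in range(n)])
    rng.shuffle(fold_id)
    return CvPlan(n, k, fold_id, seed)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    import warnings

    with warnings.catch_warnings():
        # (near-)constant inputs are already mapped to NaN above; scipy's
        # warning for borderline cases is redundant here
        warnings.simplefilter("ignore")
        return float(stats.pearsonr(a, b).statistic)


def pcc(observed, predicted, mode: str = "together", plan: CvPlan | None = None):
    """Pearson correlation of predictions: pooled or per test fold.

    ``together`` consolidates every test fold before one correlation;
    ``separate`` returns one correlation per fold (requires a plan).  A
    zero-variance vector yields NaN (undefined correlation).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must be aligned")
    if mode == "together":
        return _pearson(observed, predicted)
    if mode == "separate":
        if plan is None:
            raise ValueError("separate mode requires a CvPlan")
        return [
            _pearson(observed[plan.test_indices(f)], predicted[plan.test_indices(f)])
            for f in range(plan.k)
        ]
    raise ValueError(f"unknown mode {mode!r}")


def relative_efficiency(observed, predicted, k: int, minimize: bool = False) -> float:
    """Realized top-k genetic gain under the predicted ranking, relative to
    the gain under the observed (oracle) ranking.

    RE(k) = (mean y of top-k by prediction - overall mean)
          / (mean y of top-k by observation - overall mean).
    Ties are broken by stable sample order.  With ``minimize`` the *lowest*
    values are selected (traits improved downwards).  Returns NaN when the
    oracle gain is zero.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    n = len(y)
    if not (1 <= k < n):
        raise ValueError(f"need 1 <= k < n, got k={k}, n={n}")
    sign = 1.0 if not minimize else -1.0
    top_pred = np.argsort(-sign * yhat, kind="stable")[:k]
    top_obs = np.argsort(-sign * y, kind="stable")[:k]
    mean_all = y.mean()
    denom = y[top_obs].mean() - mean_all
    if denom == 0:
        return float("nan")
    return float((y[top_pred].mean() - mean_all) / denom)


def re_curve(observed, predicted, ks, minimize: bool = False) -> dict[int, float]:
    return {int(k): relative_efficiency(observed, predicted, int(k), minimize) for k in ks}


def paired_t(metric_a, metric_b) -> tuple[float, float]:
    """Paired t test on fold-wise metric differences; NaN when the
    differences have zero variance."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return (0.0 if np.allclose(d, 0) else float("inf"), float("nan"))
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def heritability_of_subset(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    snp_ids: list[str],
) -> float:
    """Proportion of phenotypic variance explained by the given SNPs:
    sigma_g^2 / (sigma_g^2 + sigma_e^2) from a REML fit on the GRM restricted
    to the subset."""
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("SNP subset must be non-empty")
    fit = fit_gblup(genotypes, phenotypes, snp_subset=snp_ids)
    return fit.variance.heritability


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    fit_predict,
    k: int = 5,
    seed: int = 0,
    model: str = "",
) -> CvResult:
    """Generic k-fold CV: ``fit_predict(train_gm, train_ph, test_gm)`` must
    return test-set predictions.  Every sample is predicted exactly once."""
    n = genotypes.n_samples
    plan = make_folds(n, k, seed)
    y = np.asarray(phenotypes.values, dtype=float)
    preds = np.full(n, np.nan)
    for f in range(k):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        gm_tr = GenotypeMatrix(
            [genotypes.samples[i] for i in tr], genotypes.snps, genotypes.codes[tr]
        )
        gm_te = GenotypeMatrix(
            [genotypes.samples[i] for i in te], genotypes.snps, genotypes.codes[te]
        )
        ph_tr = PhenotypeVector(phenotypes.trait, y[tr])
        preds[te] = np.asarray(fit_predict(gm_tr, ph_tr, gm_te), dtype=float)
    result = CvResult(plan, y, preds, model)
    result.per_fold_pcc = pcc(y, preds, "separate", plan)
    result.pooled_pcc = pcc(y, preds, "together")
    return result
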