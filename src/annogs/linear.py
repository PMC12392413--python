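"""Mixed-model genomic predictors: GBLUP, ridge-regression BLUP, MultiBLUP.

All three model the phenotype as an overall mean plus genetic value(s) and
residual, ``y = mu + g + e`` with ``g ~ N(0, K sigma_g^2)`` and the genomic
relationship matrix ``K = ZZ'/p`` on column-centered dosage codes (centering
by twice the allele frequency).  Variance components are estimated by REML:
a single genetic component is profiled on the eigendecomposition of K and
optimized in the variance ratio; multiple components use bounded
quasi-Newton on log variance ratios.  Marker effects are back-solved from
the genetic values, so fitted models predict new samples through
``mu + Z_new u``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .io import GenotypeMatrix, PhenotypeVector

__all__ = [
    "Grm",
    "VarianceComponents",
    "MixedModelFit",
    "compute_grm",
    "fit_gblup",
    "fit_rrblup",
    "fit_multiblup",
]

logger = logging.getLogger(__name__)

_LL_TOL = 1e-8


@dataclass
class Grm:
    """Genomic relationship matrix K = ZZ'/p on centered codes."""

    matrix: np.ndarray
    p: int
    snp_ids: list[str]


@dataclass
class VarianceComponents:
    sigma_g2: list[float]  # one per genetic component
    sigma_e2: float
    log_likelihood: float
    # mean diagonal of each component's K: puts sigma_g2 on the phenotypic
    # scale (K = ZZ'/p is not normalized to unit diagonal)
    k_diag_means: list[float] = None

    @property
    def heritability(self) -> float:
        scales = self.k_diag_means or [1.0] * len(self.sigma_g2)
        g = sum(s * c for s, c in zip(self.sigma_g2, scales))
        return g / (g + self.sigma_e2) if g + self.sigma_e2 > 0 else 0.0


@dataclass
class MixedModelFit:
    mu_hat: float
    genetic_values: np.ndarray
    snp_effects: np.ndarray  # aligned with snp_ids
    snp_ids: list[str]
    variance: VarianceComponents
    column_means: np.ndarray  # training-set centering, aligned with snp_ids

    @property
    def predictions(self) -> np.ndarray:
        return self.mu_hat + self.genetic_values

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Predict new samples via back-solved marker effects."""
        gm = genotypes.subset_snps(self.snp_ids)
        Z = gm.codes.astype(float) - self.column_means
        return self.mu_hat + Z @ self.snp_effects


def _centered(genotypes: GenotypeMatrix, snp_subset=None):
    gm = genotypes if snp_subset is None else genotypes.subset_snps(list(snp_subset))
    codes = gm.codes.astype(float)
    means = codes.mean(axis=0)
    return codes - means, means, gm.snps.snp_ids


def compute_grm(genotypes: GenotypeMatrix, snp_subset=None) -> Grm:
    """K = ZZ'/p on column-centered codes."""
    if snp_subset is not None and len(list(snp_subset)) == 0:
        raise ValueError("SNP subset must be non-empty")
    Z, _, ids = _centered(genotypes, snp_subset)
    p = Z.shape[1]
    if p == 0:
        raise ValueError("SNP subset must be non-empty")
    return Grm(Z @ Z.T / p, p, ids)


def _reml_single(d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Profile REML for V = sigma_e^2 (I + phi K), K = U diag(d) U'.

    ``yt`` and ``xt`` are y and the intercept column rotated by U'.  Returns
    (phi, sigma_e2, mu_hat, log_likelihood).
    """
    n = len(yt)

    def profile(phi: float):
        w = 1.0 + phi * d
        xw = xt / w
        sxx = float(xw @ xt)
        mu = float(xw @ yt) / sxx
        r = yt - mu * xt
        se2 = float((r / w) @ r) / (n - 1)
        ll = -0.5 * (
            (n - 1) * (np.log(2 * np.pi * se2) + 1.0)
            + float(np.sum(np.log(w)))
            + np.log(sxx)
        )
        return ll, se2, mu

    def neg(t: float) -> float:
        return -profile(np.exp(t))[0]

    res = minimize_scalar(neg, bounds=(-25.0, 25.0), method="bounded",
                          options={"xatol": 1e-12})
    phi = float(np.exp(res.x))
    ll, se2, mu = profile(phi)
    ll0, se20, mu0 = profile(0.0)
    if ll0 >= ll - _LL_TOL:
        logger.info("REML at boundary: genetic variance estimated at 0")
        return 0.0, se20, mu0, ll0
    return phi, se2, mu, ll


def fit_gblup(genotypes: GenotypeMatrix, phenotypes: PhenotypeVector,
              snp_subset=None) -> MixedModelFit:
    """Single-component GBLUP with REML variance components."""
    if genotypes.n_samples < 3:
        raise ValueError("GBLUP requires at least 3 samples")
    Z, means, ids = _centered(genotypes, snp_subset)
    y = np.asarray(phenotypes.values, dtype=float)
    p = Z.shape[1]
    K = Z @ Z.T / p
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(len(y))
    phi, se2, mu, ll = _reml_single(d, yt, xt)
    sg2 = phi * se2
    w = 1.0 + phi * d
    rt = yt - mu * xt
    ghat = U @ (phi * d / w * rt)
    u_eff = (phi / p) * (Z.T @ (U @ (rt / w)))
    var = VarianceComponents([sg2], se2, ll, [float(np.mean(np.diag(K)))])
    return MixedModelFit(mu, ghat, u_eff, ids, var, means)


def fit_rrblup(genotypes: GenotypeMatrix, phenotypes: PhenotypeVector,
               snp_subset=None) -> MixedModelFit:
    """Ridge-regression BLUP: u = (Z'Z + lambda I)^-1 Z'(y - mu).

    The ridge parameter lambda = sigma_e^2 / sigma_u^2 comes from the same
    REML fit as GBLUP (sigma_u^2 = sigma_g^2 / p), which makes the two
    models' predictions identical under the matched scaling.
    """
    if genotypes.n_samples < 3:
        raise ValueError("rrBLUP requires at least 3 samples")
    Z, means, ids = _centered(genotypes, snp_subset)
    y = np.asarray(phenotypes.values, dtype=float)
    n, p = Z.shape
    K = Z @ Z.T / p
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    phi, se2, mu, ll = _reml_single(d, yt, xt)
    r = y - mu
    if phi == 0.0:
        u_eff = np.zeros(p)
    else:
        lam = p / phi  # sigma_e^2 / sigma_u^2 on the marker scale
        if p <= n:
            u_eff = np.linalg.solve(Z.T @ Z + lam * np.eye(p), Z.T @ r)
        else:  # Woodbury form for p >> n
            u_eff = Z.T @ np.linalg.solve(Z @ Z.T + lam * np.eye(n), r)
    var = VarianceComponents([phi * se2], se2, ll, [float(np.mean(np.diag(K)))])
    return MixedModelFit(mu, Z @ u_eff, u_eff, ids, var, means)


def fit_multiblup(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    snp_classes: dict[str, list[str]],
) -> MixedModelFit:
    """BLUP with one genetic variance component per SNP class.

    ``snp_classes`` maps a class label to its SNP ids; classes must be
    disjoint and cover all SNPs of interest.  Empty classes are dropped with
    a warning.  V = sum_m sigma_m^2 K^m + sigma_e^2 I is fitted by REML on
    log variance ratios.
    """
    classes = {lab: list(ids) for lab, ids in snp_classes.items()}
    for lab in [lab for lab, ids in classes.items() if not ids]:
        logger.warning("dropping empty SNP class %r", lab)
        del classes[lab]
    if not classes:
        raise ValueError("no non-empty SNP classes")
    labels = sorted(classes)
    if len(labels) == 1:
        fit = fit_gblup(genotypes, phenotypes, snp_subset=classes[labels[0]])
        return fit
    all_seen: set[str] = set()
    for lab in labels:
        dup = all_seen & set(classes[lab])
        if dup:
            raise ValueError(f"SNP classes overlap: {sorted(dup)[:5]}")
        all_seen |= set(classes[lab])

    y = np.asarray(phenotypes.values, dtype=float)
    n = len(y)
    Zs, means_, ids_ = {}, {}, {}
    Ks = {}
    for lab in labels:
        Z, means, ids = _centered(genotypes, classes[lab])
        Zs[lab], means_[lab], ids_[lab] = Z, means, ids
        Ks[lab] = Z @ Z.T / Z.shape[1]
    ones = np.ones(n)

    def profile(phis: np.ndarray):
        V0 = np.eye(n)
        for lab, phi in zip(labels, phis):
            V0 = V0 + phi * Ks[lab]
        from scipy.linalg import cho_solve

        c = np.linalg.cholesky(V0)
        Vy = cho_solve((c, True), y)
        Vx = cho_solve((c, True), ones)
        sxx = float(ones @ Vx)
        mu = float(ones @ Vy) / sxx
        r = y - mu * ones
        Vr = Vy - mu * Vx
        se2 = float(r @ Vr) / (n - 1)
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        ll = -0.5 * (
            (n - 1) * (np.log(2 * np.pi * se2) + 1.0) + logdet + np.log(sxx)
        )
        return ll, se2, mu, Vr

    def neg(t: np.ndarray) -> float:
        return -profile(np.exp(t))[0]

    t0 = np.zeros(len(labels))
    res = minimize(neg, t0, method="L-BFGS-B", bounds=[(-20, 20)] * len(labels),
                   options={"ftol": _LL_TOL, "gtol": 1e-10})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"REML did not converge: {res.message}")
    phis = np.exp(res.x)
    # boundary check: components driven to the lower bound are reported as 0
    phis[res.x <= -20 + 1e-9] = 0.0
    ll, se2, mu, Vr = profile(phis)
    sg2 = [float(phi * se2) for phi in phis]
    genetic = np.zeros(n)
    eff_all, ids_all, means_all = [], [], []
    for lab, phi in zip(labels, phis):
        p_m = Zs[lab].shape[1]
        u_m = (phi / p_m) * (Zs[lab].T @ (Vr / se2)) * se2
        genetic += Zs[lab] @ u_m
        eff_all.append(u_m)
        ids_all += ids_[lab]
        means_all.append(means_[lab])
    var = VarianceComponents(
        sg2, float(se2), float(ll),
        [float(np.mean(np.diag(Ks[lab]))) for lab in labels],
    )
    return MixedModelFit(
        float(mu), genetic, np.concatenate(eff_all), ids_all, var,
        np.concatenate(means_all),
    )
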