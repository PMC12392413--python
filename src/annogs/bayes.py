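"""BayesR mixture-prior Gibbs sampling, its class-specific extension, and the
annotation-derived disjoint SNP classes.

SNP effects follow a 4-component zero-mean normal mixture with variances
fixed at (0, 1e-4, 1e-3, 1e-2) x sigma_g^2 (null / small / medium / large);
the mixing proportions carry a flat Dirichlet(1,1,1,1) prior.  The
class-specific variant gives each disjoint SNP class its own mixture
proportions.  The sampler cycles the intercept, per-SNP component indicator
and effect (component marginalized over the effect, then the effect drawn
from its conditional normal), the proportions, and the two variance
components under weakly informative scaled-inverse-chi-square priors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnnotationBundle, GenotypeMatrix, PhenotypeVector, SnpTable

__all__ = [
    "BayesRResult",
    "SnpClassAssignment",
    "build_disjoint_classes",
    "fit_bayesr",
    "fit_bayesrc",
    "CLASS_LABELS",
]

MIXTURE_SCALES = np.array([0.0, 1e-4, 1e-3, 1e-2])
CLASS_LABELS = ("I", "II", "III", "IV", "V")
_PRIOR_DF = 4.0
_WINDOW_50KB = 50_000


@dataclass
class BayesRResult:
    """Posterior summaries of a BayesR / class-specific BayesR chain."""

    mu: float
    beta: pd.Series  # posterior-mean effect per SNP
    pip: pd.Series  # posterior probability of a non-null component per SNP
    pi: pd.DataFrame  # classes x 4 posterior-mean mixing proportions
    sigma_g2: float
    sigma_e2: float
    predictions: np.ndarray
    column_means: np.ndarray

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        gm = genotypes.subset_snps(list(self.beta.index))
        X = gm.codes.astype(float) - self.column_means
        return self.mu + X @ self.beta.to_numpy()


@dataclass
class SnpClassAssignment:
    """Disjoint SNP classes I-V from nonsynonymous / conserved / signature
    annotation categories."""

    frame: pd.DataFrame  # columns: snp_id, category (a/b), class_label

    def as_dict(self) -> dict[str, list[str]]:
        return {
            lab: grp["snp_id"].tolist()
            for lab, grp in self.frame.groupby("class_label", observed=False)
        }

    def labels_for(self, snp_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.frame["snp_id"], self.frame["class_label"]))
        return np.array([lookup[s] for s in snp_ids])


def _gene_windows(bundle: AnnotationBundle, flags: pd.Series, pad: int):
    genes = bundle.gene_intervals
    sel = genes[genes["gene_id"].map(lambda g: bool(flags.get(g, False)))]
    return (
        sel["chrom"].to_numpy(),
        sel["start"].to_numpy() - pad,
        sel["end"].to_numpy() + pad,
    )


def _in_windows(chrom: str, pos0: int, windows) -> bool:
    chroms, starts, ends = windows
    hit = (chroms == chrom) & (starts <= pos0) & (pos0 < ends)
    return bool(hit.any())


def build_disjoint_classes(snps: SnpTable, bundle: AnnotationBundle) -> SnpClassAssignment:
    """Assign each SNP to exactly one of five disjoint classes.

    Categories: (a) nonsynonymous SNPs, (b) all other SNPs, (c) conserved
    genes, (d) metaterm signature genes.  Classes: I = (a) within a (c)
    gene; II = (a) within a (d) gene; III = (b) within +-50 kb of a (c)
    gene; IV = (b) within +-50 kb of a (d) gene; V = the rest.  Precedence
    I > II > III > IV > V makes the partition disjoint.
    """
    cons0 = _gene_windows(bundle, bundle.conserved_gene_flags, 0)
    sig0 = _gene_windows(bundle, bundle.signature_gene_flags, 0)
    cons50 = _gene_windows(bundle, bundle.conserved_gene_flags, _WINDOW_50KB)
    sig50 = _gene_windows(bundle, bundle.signature_gene_flags, _WINDOW_50KB)
    rows = []
    for row in snps.frame.itertuples(index=False):
        pos0 = row.pos - 1
        is_a = bool(row.nonsynonymous_flag)
        if is_a and _in_windows(row.chrom, pos0, cons0):
            lab = "I"
        elif is_a and _in_windows(row.chrom, pos0, sig0):
            lab = "II"
        elif not is_a and _in_windows(row.chrom, pos0, cons50):
            lab = "III"
        elif not is_a and _in_windows(row.chrom, pos0, sig50):
            lab = "IV"
        else:
            lab = "V"
        rows.append((row.snp_id, "a" if is_a else "b", lab))
    return SnpClassAssignment(pd.DataFrame(rows, columns=["snp_id", "category", "class_label"]))


def _gibbs(
    X: np.ndarray,
    y: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    burnin: int,
    numit: int,
    seed: int,
    fixed_variances: tuple[float, float] | None = None,
):
    """Shared Gibbs core; class_idx selects each SNP's mixture-proportion row.

    ``fixed_variances`` pins (sigma_g2, sigma_e2) instead of sampling them,
    which makes the posterior comparable to low-dimensional quadrature."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    xtx = (X**2).sum(axis=0)
    xtx[xtx == 0] = 1e-12
    vary = float(np.var(y))
    # scaled-inverse-chi-square hyperpriors centred on half the phenotypic
    # variance each (prior mean = scale * df / (df - 2))
    s_g = vary / 2 * (_PRIOR_DF - 2) / _PRIOR_DF
    s_e = vary / 2 * (_PRIOR_DF - 2) / _PRIOR_DF

    mu = float(np.mean(y))
    beta = np.zeros(p)
    comp = np.zeros(p, dtype=int)
    pi = np.full((n_classes, 4), 0.25)
    sg2 = vary / 2
    se2 = vary / 2
    if fixed_variances is not None:
        sg2, se2 = fixed_variances
    e = y - mu  # residual with all beta = 0

    beta_sum = np.zeros(p)
    nonnull_sum = np.zeros(p)
    pi_sum = np.zeros((n_classes, 4))
    mu_sum = 0.0
    sg2_sum = 0.0
    se2_sum = 0.0
    kept = 0

    for it in range(numit):
        # intercept
        e += mu
        mu = rng.normal(e.mean(), np.sqrt(se2 / n))
        e -= mu
        # SNP effects and indicators
        log_pi = np.log(np.maximum(pi, 1e-300))
        for j in range(p):
            xj = X[:, j]
            if beta[j] != 0.0:
                e += xj * beta[j]
            rhs = float(xj @ e)
            cj = class_idx[j]
            logp = np.empty(4)
            logp[0] = log_pi[cj, 0]
            for k in range(1, 4):
                vk = MIXTURE_SCALES[k] * sg2
                c = xtx[j] + se2 / vk
                logp[k] = (
                    log_pi[cj, k]
                    - 0.5 * np.log(vk * c / se2)
                    + 0.5 * rhs**2 / (se2 * c)
                )
            logp -= logp.max()
            prob = np.exp(logp)
            prob /= prob.sum()
            k = int(rng.choice(4, p=prob))
            comp[j] = k
            if k == 0:
                beta[j] = 0.0
            else:
                vk = MIXTURE_SCALES[k] * sg2
                c = xtx[j] + se2 / vk
                mean = rhs / c
                beta[j] = rng.normal(mean, np.sqrt(se2 / c))
                e -= xj * beta[j]
        # mixing proportions, per class
        for cidx in range(n_classes):
            sel = class_idx == cidx
            counts = np.bincount(comp[sel], minlength=4)
            pi[cidx] = rng.dirichlet(1.0 + counts)
        if fixed_variances is None:
            # genetic variance from the scaled effects
            nz = comp > 0
            df_g = _PRIOR_DF + nz.sum()
            ssq = float(np.sum(beta[nz] ** 2 / MIXTURE_SCALES[comp[nz]])) if nz.any() else 0.0
            sg2 = (ssq + _PRIOR_DF * s_g) / rng.chisquare(df_g)
            # residual variance
            se2 = (float(e @ e) + _PRIOR_DF * s_e) / rng.chisquare(_PRIOR_DF + n)
        if it >= burnin:
            kept += 1
            beta_sum += beta
            nonnull_sum += (comp > 0).astype(float)
            pi_sum += pi
            mu_sum += mu
            sg2_sum += sg2
            se2_sum += se2

    return (
        mu_sum / kept,
        beta_sum / kept,
        nonnull_sum / kept,
        pi_sum / kept,
        sg2_sum / kept,
        se2_sum / kept,
    )


def fit_bayesr(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    burnin: int = 5000,
    numit: int = 10000,
    seed: int = 0,
    fixed_variances: tuple[float, float] | None = None,
) -> BayesRResult:
    """Single-class BayesR: one shared mixture-proportion vector."""
    if numit <= burnin:
        raise ValueError("numit must exceed burnin")
    X = genotypes.codes.astype(float)
    means = X.mean(axis=0)
    Xc = X - means
    y = np.asarray(phenotypes.values, dtype=float)
    mu, beta, pip, pi, sg2, se2 = _gibbs(
        Xc, y, np.zeros(Xc.shape[1], dtype=int), 1, burnin, numit, seed,
        fixed_variances,
    )
    ids = pd.Index(genotypes.snps.snp_ids)
    return BayesRResult(
        mu=float(mu),
        beta=pd.Series(beta, index=ids),
        pip=pd.Series(pip, index=ids),
        pi=pd.DataFrame(pi, index=["all"], columns=["null", "small", "medium", "large"]),
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        predictions=mu + Xc @ beta,
        column_means=means,
    )


def fit_bayesrc(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    classes: SnpClassAssignment,
    burnin: int = 5000,
    numit: int = 10000,
    seed: int = 0,
) -> BayesRResult:
    """Class-specific BayesR: an independent Dirichlet(1,1,1,1) mixture
    proportion vector per disjoint SNP class."""
    if numit <= burnin:
        raise ValueError("numit must exceed burnin")
    X = genotypes.codes.astype(float)
    means = X.mean(axis=0)
    Xc = X - means
    y = np.asarray(phenotypes.values, dtype=float)
    snp_ids = genotypes.snps.snp_ids
    labels = classes.labels_for(snp_ids)
    present = [lab for lab in CLASS_LABELS if lab in set(labels)] or ["all"]
    lab_index = {lab: i for i, lab in enumerate(present)}
    class_idx = np.array([lab_index[lab] for lab in labels])
    mu, beta, pip, pi, sg2, se2 = _gibbs(
        Xc, y, class_idx, len(present), burnin, numit, seed
    )
    ids = pd.Index(snp_ids)
    # a class with no SNPs has posterior = prior: report the Dirichlet(1,1,1,1)
    # mean exactly
    pi_frame = pd.DataFrame(
        0.25, index=list(CLASS_LABELS), columns=["null", "small", "medium", "large"]
    )
    pi_frame.loc[present, :] = pi
    return BayesRResult(
        mu=float(mu),
        beta=pd.Series(beta, index=ids),
        pip=pd.Series(pip, index=ids),
        pi=pi_frame,
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        predictions=mu + Xc @ beta,
        column_means=means,
    )
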