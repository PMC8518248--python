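"""Covariate-adjusted differential expression and cohort-level statistics.

Per-feature ordinary least squares of expression on a disease-group
indicator plus covariates, with optional empirical-Bayes variance
moderation (a scaled-F prior on the residual variances; the posterior
variance is a weighted average of each feature's own variance and the
prior, weighted by their degrees of freedom). Also houses the clinical
trait association (severity score within the disease arm, with plain and
partial Spearman correlations), the 2×2 and rank-sum tests used for
cohort tables, and a PCA-based multivariate permutation test of group
separation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma

from .containers import ExpressionMatrix, validate_subjects
from .stats_utils import bh_fdr, perm_pvalue, spearman

__all__ = [
    "DesignError",
    "ModerationParams",
    "bh_fdr",
    "build_design",
    "contingency_test",
    "fit_group_de",
    "moderate_variances",
    "multivariate_group_separation",
    "partial_spearman",
    "rank_sum_test",
    "trait_association",
    "zscore_features",
]


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable design matrices."""


def build_design(
    subjects: pd.DataFrame, covariates=("age", "sex"), group_column: str | None = "group"
) -> pd.DataFrame:
    """Intercept + disease indicator + covariates, categorical ones dummy-coded."""
    cols = {"intercept": np.ones(len(subjects))}
    if group_column is not None:
        cols["group_disease"] = (subjects[group_column] == "disease").astype(float)
    design = pd.DataFrame(cols, index=subjects.index)
    for cov in covariates:
        col = subjects[cov]
        if col.isna().any():
            raise DesignError(f"covariate {cov!r} has missing values")
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
        else:
            design[cov] = col.astype(float)
    x = design.to_numpy(float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        _, r, piv = linalg.qr(x, pivoting=True, mode="economic")
        tol = np.abs(r[0, 0]) * max(x.shape) * np.finfo(float).eps
        aliased = [design.columns[piv[i]] for i in range(x.shape[1]) if abs(r[i, i]) < tol]
        raise DesignError(f"rank-deficient design; aliased column(s): {aliased}")
    return design


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``d0`` (prior df; ``inf`` means complete shrinkage, 0 disables it),
    ``s0_sq`` (prior variance) and the per-feature posterior variances
    s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g).
    """

    d0: float
    s0_sq: float
    posterior_var: np.ndarray


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s_sq: np.ndarray, d: float) -> ModerationParams:
    """Fit the scaled-F prior to residual variances by moments on log s².

    Method-of-moments closed forms on z = log s²: the excess of the
    sample variance of z over trigamma(d/2) estimates trigamma(d0/2);
    no excess dispersion drives d0 to infinity (all posterior variances
    equal the prior variance).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if len(s_sq) < 3:
        raise ValueError("variance moderation needs at least 3 features")
    if (s_sq <= 0).any():
        raise ValueError("residual variances must be positive")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    z = np.log(s_sq)
    e = z - digamma(d / 2) + np.log(d / 2)
    emean = float(e.mean())
    n = len(e)
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(polygamma(1, d / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
        post = (d0 * s0_sq + d * s_sq) / (d0 + d)
    else:
        d0 = np.inf
        s0_sq = float(s_sq.mean())
        post = np.full_like(s_sq, s0_sq)
    return ModerationParams(d0=d0, s0_sq=s0_sq, posterior_var=post)


def group_ols_stats(x: np.ndarray, y: np.ndarray, moderate: bool = True):
    """Vectorized per-feature OLS; the coefficient of interest is column 1.

    ``x`` is the (samples × parameters) design, ``y`` the
    (features × samples) data. Returns ``(effect, t, p, s2, df)``.
    Shared by the user-facing fit and the permutation refits so observed
    and permuted passes use the identical computation.
    """
    n, k = x.shape
    d = n - k
    if d < 1:
        raise DesignError("no residual degrees of freedom")
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    resid = y - beta @ x.T
    s2 = (resid**2).sum(axis=1) / d
    c = np.linalg.inv(x.T @ x)[1, 1]
    effect = beta[:, 1]
    if moderate:
        params = moderate_variances(s2, d)
        var = params.posterior_var
        df = d + params.d0
    else:
        var = s2
        df = float(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var * c)
    if np.isinf(df):
        pvals = 2 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2 * stats.t.sf(np.abs(t), df)
    return effect, t, pvals, s2, df


def fit_group_de(
    matrix: ExpressionMatrix,
    subjects: pd.DataFrame,
    covariates=("age", "sex"),
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-feature OLS of expression on disease indicator + covariates.

    Returns a DataFrame indexed by feature id with columns ``effect``
    (log2 disease − control difference), ``t``, ``p``, ``fdr``,
    ``direction``, ``df`` and ``s2`` (residual variance). With
    ``moderate=True`` the t uses the empirical-Bayes posterior variance
    and d0 extra degrees of freedom.
    """
    validate_subjects(subjects)
    missing = matrix.sample_ids.difference(subjects.index)
    if len(missing):
        raise DesignError(f"samples without subject rows: {list(missing[:5])}")
    subj = subjects.loc[matrix.sample_ids]
    design = build_design(subj, covariates)
    x = design.to_numpy(float)
    y = matrix.to_numpy()
    effect, t, pvals, s2, df = group_ols_stats(x, y, moderate)
    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t,
            "p": pvals,
            "fdr": bh_fdr(pvals),
            "direction": np.where(effect >= 0, "up", "down"),
            "df": df,
            "s2": s2,
        },
        index=matrix.feature_ids,
    )
    return out


def partial_spearman(x, y, covariates) -> float:
    """Partial Spearman via rank-residual correlation.

    Ranks x, y and the covariates, regresses the x- and y-ranks on the
    covariate ranks (with intercept) and returns the Pearson correlation
    of the residuals. Reduces exactly to plain Spearman when the
    covariates are constant.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.atleast_2d(np.asarray(covariates, float))
    if cov.shape[0] == len(x) and cov.ndim == 2 and cov.shape[1] != len(x):
        cov = cov.T
    n = len(x)
    if n < 4:
        raise ValueError("partial Spearman needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) x or y")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(c) for c in cov])
    z = np.column_stack([np.ones(n), rc])
    h = z @ np.linalg.pinv(z)
    ex = rx - h @ rx
    ey = ry - h @ ry
    # a rank vector fully explained by the covariate ranks leaves only
    # round-off residuals; call that zero partial correlation
    tol = 1e-10 * n**2
    if (ex**2).sum() < tol or (ey**2).sum() < tol:
        return 0.0
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    return float(np.clip((ex * ey).sum() / denom, -1.0, 1.0))


def trait_association(
    matrix: ExpressionMatrix,
    subjects: pd.DataFrame,
    trait: str = "mrss",
    covariates=("age", "sex"),
) -> pd.DataFrame:
    """Per-feature association with a clinical trait in the disease arm.

    p comes from the trait coefficient of expression ~ trait + covariates;
    ``rho`` is the plain Spearman with the trait, ``rho_part`` the partial
    Spearman adjusting for the covariates; FDR is BH on the model p.
    """
    subj = subjects.loc[matrix.sample_ids]
    has_trait = subj[trait].notna()
    subj = subj[has_trait]
    if len(subj) < 4:
        raise DesignError("too few samples with the trait")
    tvals = subj[trait].astype(float)
    if tvals.nunique() <= 1:
        raise DesignError(f"trait {trait!r} is constant")
    sub = matrix.subset_samples(subj.index)
    design = build_design(subj, covariates, group_column=None)
    design.insert(1, "trait", tvals)
    x = design.to_numpy(float)
    y = sub.to_numpy()
    n, p = x.shape
    d = n - p
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    resid = y - beta @ x.T
    s2 = (resid**2).sum(axis=1) / d
    c = np.linalg.inv(x.T @ x)[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / np.sqrt(s2 * c)
    pvals = 2 * stats.t.sf(np.abs(t), d)
    cov_mat = design.to_numpy(float)[:, 2:]
    rhos = np.empty(len(sub.feature_ids))
    rhos_part = np.empty(len(sub.feature_ids))
    tv = tvals.to_numpy()
    for i, row in enumerate(y):
        rhos[i] = spearman(row, tv)
        rhos_part[i] = partial_spearman(row, tv, cov_mat.T) if cov_mat.shape[1] else rhos[i]
    return pd.DataFrame(
        {
            "slope": beta[:, 1],
            "p": pvals,
            "rho": rhos,
            "rho_part": rhos_part,
            "fdr": bh_fdr(pvals),
        },
        index=sub.feature_ids,
    )


def contingency_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected Pearson χ² on a 2×2 table [[a, b], [c, d]].

    The Yates term |o − e| − 0.5 is clamped at 0, so near-null tables give
    χ² = 0, p = 1. Returns (chi2, p); df = 1, two-sided.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin in 2x2 table")
    exp = np.outer(row, col) / obs.sum()
    diff = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    chi2 = float((diff**2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p.

    Exact enumeration for small tie-free samples (n_x + n_y ≤ 20),
    normal approximation with tie correction and continuity otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def zscore_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature standardization (mean 0, sd 1 with n−1 denominator)."""
    vals = matrix.values
    sd = vals.std(axis=1, ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance feature(s): {list(zero.index[:5])}")
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, matrix.layer)


def multivariate_group_separation(
    matrix: ExpressionMatrix,
    groups: pd.Series,
    k_components: int = 2,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Permutation test of multivariate group separation in PCA space.

    Features are z-scored, samples are projected onto the first
    ``k_components`` principal components, and a two-sample Hotelling T²
    is computed on the scores; the null is built by permuting group
    labels over the fixed scores. Returns a dict with ``t2``, ``p`` and
    the component count.
    """
    groups = groups.reindex(matrix.sample_ids)
    labels = groups.to_numpy()
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    n = matrix.shape[1]
    if k_components >= n:
        raise ValueError("k_components must be smaller than the sample count")
    for g in uniq:
        if (labels == g).sum() <= k_components:
            raise ValueError(f"group {g!r} needs more than {k_components} samples")
    z = zscore_features(matrix).to_numpy()
    # samples-by-features SVD; scores = first k right singular directions
    xs = z.T - z.T.mean(axis=0)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    scores = u[:, :k_components] * s[:k_components]

    def hotelling(lab):
        a = scores[lab == uniq[0]]
        b = scores[lab == uniq[1]]
        na, nb = len(a), len(b)
        diff = a.mean(axis=0) - b.mean(axis=0)
        sp = ((na - 1) * np.cov(a, rowvar=False) + (nb - 1) * np.cov(b, rowvar=False)) / (
            na + nb - 2
        )
        sp = np.atleast_2d(sp)
        return float(na * nb / (na + nb) * diff @ np.linalg.solve(sp, diff))

    t2_obs = hotelling(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = hotelling(rng.permutation(labels))
    return {"t2": t2_obs, "p": perm_pvalue(null, t2_obs, "greater"), "k": k_components}
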