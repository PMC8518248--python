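"""Between-sample similarity matrices and Mantel-style concordance tests.

A layer's similarity matrix holds Spearman correlations between every
pair of sample profiles, computed over all features (no selection, to
avoid variable-selection bias). Concordance between two layers is the
Spearman correlation of the strictly-upper-triangle entries, tested by
randomly permuting the assignment of samples to subjects in one layer
(rows and columns jointly).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .stats_utils import perm_pvalue, spearman


@dataclass
class SimilarityMatrix:
    """Symmetric subject × subject similarity (Spearman), diagonal 1."""

    values: pd.DataFrame
    layer: str

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class MantelResult:
    rho_obs: float
    n_subjects: int
    n_perm: int
    null_rhos: np.ndarray
    p: float


def sample_similarity(matrix: ExpressionMatrix, subjects=None) -> SimilarityMatrix:
    """Pairwise Spearman correlation between full sample profiles."""
    vals = matrix.values if subjects is None else matrix.values[list(subjects)]
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for a similarity matrix")
    const = vals.columns[vals.nunique(axis=0) <= 1]
    if len(const):
        raise ValueError(f"constant sample profile(s): {list(const[:5])}")
    ranks = vals.rank(axis=0).to_numpy()
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=0))
    sim = (ranks.T @ ranks) / np.outer(norm, norm)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(
        pd.DataFrame(sim, index=vals.columns, columns=vals.columns), matrix.layer
    )


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    s_a: SimilarityMatrix,
    s_b: SimilarityMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
    alternative: str = "two-sided",
    method: str = "spearman",
) -> MantelResult:
    """Concordance of two similarity matrices over the same subjects.

    rho_obs correlates the strictly-upper-triangle entries
    (Spearman by default, Pearson optional); the null permutes the
    subject-to-sample assignment of layer b, applying each permutation to
    rows and columns jointly. Two-sided p with the add-one rule.
    """
    if not s_a.subject_ids.equals(s_b.subject_ids):
        common = s_a.subject_ids.intersection(s_b.subject_ids)
        if len(common) < 4:
            raise ValueError("fewer than 4 shared subjects")
        s_a = SimilarityMatrix(s_a.values.loc[common, common], s_a.layer)
        s_b = SimilarityMatrix(s_b.values.loc[common, common], s_b.layer)
    n = len(s_a.subject_ids)
    if n < 4:
        raise ValueError("need at least 4 subjects (upper triangle too small)")
    a = s_a.values.to_numpy()
    b = s_b.values.to_numpy()

    def corr(mat_b):
        va, vb = _upper(a), _upper(mat_b)
        if method == "spearman":
            return spearman(va, vb)
        return float(np.corrcoef(va, vb)[0, 1])

    rho_obs = corr(b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = corr(b[np.ix_(perm, perm)])
    p = perm_pvalue(null, rho_obs, alternative)
    return MantelResult(rho_obs=rho_obs, n_subjects=n, n_perm=n_perm, null_rhos=null, p=p)


def pairwise_concordance(
    layers: dict[str, ExpressionMatrix],
    subjects: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> pd.DataFrame:
    """The 2 (group) × 3 (layer pair) grid of Mantel tests.

    For each group and each unordered pair of layers, restricts to
    subjects with samples in both layers and runs :func:`mantel_test`.
    Cells with fewer than 4 shared subjects are marked unavailable
    (NaN rho/p) without failing the rest.
    """
    names = list(layers)
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(2 * len(pairs)))
    rows = []
    for group in ("control", "disease"):
        members = subjects.index[subjects["group"] == group]
        for la, lb in pairs:
            shared = [
                s for s in members
                if s in layers[la].sample_ids and s in layers[lb].sample_ids
            ]
            cell_seed = int(next(seeds))
            if len(shared) < 4:
                rows.append((group, la, lb, len(shared), np.nan, np.nan))
                continue
            sim_a = sample_similarity(layers[la], shared)
            sim_b = sample_similarity(layers[lb], shared)
            res = mantel_test(sim_a, sim_b, n_perm=n_perm, seed=cell_seed)
            rows.append((group, la, lb, res.n_subjects, res.rho_obs, res.p))
    return pd.DataFrame(
        rows, columns=["group", "layer_a", "layer_b", "n_subjects", "rho", "p"]
    )
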