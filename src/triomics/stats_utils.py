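"""Small statistical primitives shared across stages."""
from __future__ import annotations

import numpy as np
from scipy import stats


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of n * p_(j) / j, clipped at 1, returned in
    the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def spearman(x, y) -> float:
    """Spearman rank correlation (NaN-free inputs)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("degenerate (constant) input to Spearman correlation")
    return float(np.corrcoef(rx, ry)[0, 1])


def perm_pvalue(null: np.ndarray, observed: float, alternative: str = "greater") -> float:
    """Empirical permutation p with the add-one rule (never exactly 0)."""
    null = np.asarray(null, float)
    n = len(null)
    if alternative == "greater":
        hits = int((null >= observed).sum())
    elif alternative == "less":
        hits = int((null <= observed).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(null) >= abs(observed)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + hits) / (n + 1)
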