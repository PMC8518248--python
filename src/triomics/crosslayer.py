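"""Cross-layer comparison of differential-expression profiles.

Three analyses: (i) Spearman correlation between serum-protein and
transcript group-effect estimates on gene-mapped pairs, with a null built
by relabeling disease/control status at the subject level jointly across
layers and refitting both layers' models; (ii) sign concordance and
correlation between disease effects and trait (severity) associations
within the serum layer; (iii) per-gene correlation of expression between
the two tissues, per group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .stats_utils import bh_fdr, perm_pvalue, spearman


@dataclass
class CrossLayerResult:
    """Effect-correlation outcome: observed rho, pair count, permutation
    null sample and p, and the feature-selection rule that was applied."""

    rho_obs: float
    n_pairs: int
    selection_rule: str
    perm_rhos: np.ndarray | None = None
    p_perm: float | None = None


def _select_pairs(de_a: pd.DataFrame, pairs: pd.DataFrame, selection: str) -> pd.DataFrame:
    """Apply a selection rule to layer-a features; rule format
    ``"p:0.05"`` (raw p) or ``"fdr:0.05"`` (BH FDR) or ``"all"``."""
    if selection == "all":
        keep = pairs
    else:
        kind, _, thr = selection.partition(":")
        if kind not in ("p", "fdr") or not thr:
            raise ValueError(f"unknown selection rule {selection!r}")
        cut = float(thr)
        passing = de_a.index[de_a[kind] < cut]
        keep = pairs[pairs["protein_feature"].isin(passing)]
    return keep


def effect_correlation(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    pairs: pd.DataFrame,
    selection: str = "p:0.05",
) -> CrossLayerResult:
    """Spearman correlation of paired effect estimates.

    ``pairs`` is the protein↔transcript pairing from
    :func:`triomics.preprocess.map_features`; the selection rule is
    applied to the layer-a (serum) results before correlating.
    """
    keep = _select_pairs(de_a, pairs, selection)
    if len(keep) < 3:
        raise ValueError(
            f"fewer than 3 pairs after selection {selection!r} ({len(keep)} left)"
        )
    ea = de_a.loc[keep["protein_feature"], "effect"].to_numpy()
    eb = de_b.loc[keep["transcript_feature"], "effect"].to_numpy()
    return CrossLayerResult(rho_obs=spearman(ea, eb), n_pairs=len(keep), selection_rule=selection)


def permutation_effect_correlation(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    subjects: pd.DataFrame,
    pairs: pd.DataFrame,
    selection: str = "p:0.05",
    covariates=("age", "sex"),
    moderate: bool = True,
    n_perm: int = 9_999,
    seed: int | None = None,
    alternative: str = "greater",
) -> CrossLayerResult:
    """Effect correlation with a group-relabeling permutation null.

    Disease/control labels are permuted once per iteration at the subject
    level and carried jointly into both layers (subjects missing from a
    layer simply contribute their permuted label where present), both
    layers' models are refit, and the correlation is recomputed under the
    identical selection rule. One-sided (upper) p by default, since the
    question is positive concordance of effects.
    """
    import warnings

    from .de import build_design, group_ols_stats
    from .stats_utils import bh_fdr as _bh

    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p", stacklevel=2)

    # fixed per-layer design scaffolding; only the group indicator column
    # changes across permutations
    layers = []
    for matrix in (matrix_a, matrix_b):
        subj = subjects.loc[matrix.sample_ids]
        design = build_design(subj, covariates).to_numpy(float)
        pos = subjects.index.get_indexer(matrix.sample_ids)
        layers.append((design, matrix.to_numpy(), pos))
    ia = matrix_a.feature_ids.get_indexer(pairs["protein_feature"])
    ib = matrix_b.feature_ids.get_indexer(pairs["transcript_feature"])
    if (ia < 0).any() or (ib < 0).any():
        raise ValueError("pairs reference features absent from the matrices")

    kind, _, thr = selection.partition(":")
    cut = float(thr) if thr else None
    if selection != "all" and kind not in ("p", "fdr"):
        raise ValueError(f"unknown selection rule {selection!r}")

    def selected(p_a: np.ndarray) -> np.ndarray:
        # identical rule for the observed and every permuted pass
        if selection == "all":
            return np.ones(len(ia), bool)
        crit = p_a if kind == "p" else _bh(p_a)
        return crit[ia] < cut

    def rho_for(groups: np.ndarray):
        effects, p_a = [], None
        for li, (design, y, pos) in enumerate(layers):
            x = design.copy()
            x[:, 1] = (groups[pos] == "disease").astype(float)
            effect, _, pvals, _, _ = group_ols_stats(x, y, moderate)
            effects.append(effect)
            if li == 0:
                p_a = pvals
        keep = selected(p_a)
        if keep.sum() < 3:
            return np.nan, keep
        return spearman(effects[0][ia[keep]], effects[1][ib[keep]]), keep

    labels = subjects["group"].to_numpy()
    obs, keep_obs = rho_for(labels)
    if np.isnan(obs):
        raise ValueError(
            f"fewer than 3 pairs after selection {selection!r} on the observed labels"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i], _ = rho_for(rng.permutation(labels))
    valid = null[~np.isnan(null)]
    p = perm_pvalue(valid, obs, alternative)
    return CrossLayerResult(
        rho_obs=obs, n_pairs=int(keep_obs.sum()),
        selection_rule=selection, perm_rhos=null, p_perm=p,
    )


@dataclass
class ConcordanceCount:
    n_tested: int
    n_concordant: int
    rho: float
    p_perm: float | None = None


def disease_vs_trait_concordance(
    de_serum: pd.DataFrame,
    trait: pd.DataFrame,
    cutoff: float = 0.05,
    n_perm: int = 0,
    seed: int | None = None,
    refit=None,
) -> ConcordanceCount:
    """Agreement between disease effects and trait associations in serum.

    Over features passing FDR < ``cutoff`` in either analysis, counts
    those whose disease effect and trait slope share a sign; over all
    shared features, the Spearman correlation between the two estimate
    vectors. When ``refit`` (a callable seed -> (de, trait) on relabeled
    data) is supplied with ``n_perm`` > 0, a permutation p for the
    correlation is computed.
    """
    common = de_serum.index.intersection(trait.index)
    de = de_serum.loc[common]
    tr = trait.loc[common]
    passing = common[(de["fdr"] < cutoff) | (tr["fdr"] < cutoff)]
    signs_agree = np.sign(de.loc[passing, "effect"]) == np.sign(tr.loc[passing, "slope"])
    rho = spearman(de["effect"], tr["slope"]) if len(common) >= 3 else np.nan
    p = None
    if n_perm and refit is not None:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            de_p, tr_p = refit(rng)
            cm = de_p.index.intersection(tr_p.index)
            null[i] = spearman(de_p.loc[cm, "effect"], tr_p.loc[cm, "slope"])
        p = perm_pvalue(null, rho, "greater")
    return ConcordanceCount(
        n_tested=len(passing), n_concordant=int(signs_agree.sum()), rho=rho, p_perm=p
    )


def per_gene_cross_tissue_correlation(
    skin: ExpressionMatrix,
    pbc: ExpressionMatrix,
    fmap,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Spearman between skin and blood expression, per group.

    Genes measured in both layers are probe-collapsed to their
    highest-mean probe; correlations run across the shared subjects of
    each group separately, BH FDR within group. The result flags genes
    whose correlation sign differs between the groups.
    """
    shared = skin.sample_ids.intersection(pbc.sample_ids)
    if len(shared) == 0:
        raise ValueError("no shared subjects between the layers")

    def collapse(matrix):
        tab = fmap.for_layer(matrix.layer)
        tab = tab[tab["feature_id"].isin(matrix.feature_ids)]
        means = matrix.values.mean(axis=1)
        tab = tab.assign(mean_expr=tab["feature_id"].map(means))
        best = (
            tab.sort_values(["gene_id", "mean_expr", "feature_id"], ascending=[True, False, True])
            .drop_duplicates("gene_id")
        )
        m = matrix.values.loc[best["feature_id"]]
        m.index = best["gene_id"].to_numpy()
        return m

    sk = collapse(skin)
    pb = collapse(pbc)
    genes = sk.index.intersection(pb.index)
    rows = []
    for group in ("disease", "control"):
        cols = [s for s in shared if subjects.loc[s, "group"] == group]
        if len(cols) < 4:
            continue
        a = sk.loc[genes, cols].to_numpy()
        b = pb.loc[genes, cols].to_numpy()
        # vectorized Spearman: rank rows then Pearson row-by-row
        ra = pd.DataFrame(a).rank(axis=1).to_numpy()
        rb = pd.DataFrame(b).rank(axis=1).to_numpy()
        ra = ra - ra.mean(axis=1, keepdims=True)
        rb = rb - rb.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (ra * rb).sum(axis=1) / denom
        n = len(cols)
        # t-approximation for the Spearman p
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        from scipy import stats as sps

        pv = 2 * sps.t.sf(np.abs(tstat), n - 2)
        pv = np.where(np.isnan(pv), 1.0, np.clip(pv, 0, 1))
        sub = pd.DataFrame(
            {"gene_id": genes, "group": group, "rho": rho, "p": pv, "fdr": bh_fdr(pv), "n": n}
        )
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    wide = out.pivot(index="gene_id", columns="group", values="rho")
    if {"disease", "control"}.issubset(wide.columns):
        disc = np.sign(wide["disease"]) * np.sign(wide["control"]) < 0
        out["discordant"] = out["gene_id"].map(disc).fillna(False).astype(bool)
    else:
        out["discordant"] = False
    return out
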