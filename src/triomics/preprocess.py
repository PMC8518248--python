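"""Panel and array preprocessing.

Serum panel: analytes with more than half of their observations below the
lower limit of detection (LLOD) are excluded (with a per-analyte check
that the below-LLOD pattern is not group-imbalanced), and remaining
sub-LLOD observations are replaced by the LLOD. Transcript layers are
restricted to probes whose average platform detection p-value is below
0.01. All layers are then log2-transformed and quantile normalized, and
proteins are paired with transcripts through shared gene ids.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, FeatureMap, SchemaError
from .stats_utils import bh_fdr


@dataclass
class LlodReport:
    """Per-protein censoring summary emitted by :func:`filter_by_llod`.

    ``table`` columns: ``frac_below`` (overall), ``frac_below_disease``,
    ``frac_below_control``, ``excluded``, and — for excluded analytes —
    ``imbalance_p`` / ``imbalance_fdr`` from a two-sided Fisher exact test
    of (below vs at-or-above LLOD) × group, BH-adjusted across the
    excluded set.
    """

    table: pd.DataFrame

    @property
    def n_excluded(self) -> int:
        return int(self.table["excluded"].sum())


def filter_by_llod(
    raw: ExpressionMatrix,
    llod: pd.Series,
    groups: pd.Series | None = None,
    max_below: float = 0.5,
) -> tuple[ExpressionMatrix, LlodReport]:
    """Drop analytes with strictly more than ``max_below`` of observations
    below their LLOD across the whole cohort.

    ``groups`` maps sample id -> group label; when given, each excluded
    analyte gets a Fisher exact test for group imbalance of its censoring
    pattern, BH-corrected across the excluded analytes.
    """
    if raw.values.empty:
        raise SchemaError("cannot LLOD-filter an empty matrix")
    missing = raw.feature_ids.difference(llod.index)
    if len(missing):
        raise SchemaError(f"LLOD undefined for feature(s): {list(missing[:5])}")
    llod = llod.reindex(raw.feature_ids)
    below = raw.values.lt(llod, axis=0)
    frac = below.mean(axis=1)
    excluded = frac > max_below

    tbl = pd.DataFrame({"frac_below": frac, "excluded": excluded})
    if groups is not None:
        groups = groups.reindex(raw.sample_ids)
        for g in ("disease", "control"):
            cols = raw.sample_ids[groups == g]
            tbl[f"frac_below_{g}"] = below[cols].mean(axis=1) if len(cols) else np.nan
        pvals = {}
        d_cols = raw.sample_ids[groups == "disease"]
        c_cols = raw.sample_ids[groups == "control"]
        for feat in raw.feature_ids[excluded]:
            a = int(below.loc[feat, d_cols].sum())
            b = len(d_cols) - a
            c = int(below.loc[feat, c_cols].sum())
            d = len(c_cols) - c
            pvals[feat] = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        tbl["imbalance_p"] = pd.Series(pvals)
        if pvals:
            tbl.loc[list(pvals), "imbalance_fdr"] = bh_fdr(np.array(list(pvals.values())))
        else:
            tbl["imbalance_fdr"] = np.nan
    kept = ExpressionMatrix(raw.values.loc[~excluded], raw.layer)
    return kept, LlodReport(tbl)


def impute_llod(matrix: ExpressionMatrix, llod: pd.Series) -> ExpressionMatrix:
    """Replace every observation strictly below its analyte's LLOD by the
    LLOD (left-censoring imputation); values at or above are untouched."""
    llod = llod.reindex(matrix.feature_ids)
    if llod.isna().any():
        raise SchemaError("LLOD undefined for some features")
    vals = matrix.values.clip(lower=llod, axis=0)
    return ExpressionMatrix(vals, matrix.layer)


def filter_by_detection(
    matrix: ExpressionMatrix, detection_p: pd.DataFrame, threshold: float = 0.01
) -> ExpressionMatrix:
    """Keep probes whose mean detection p-value across samples is strictly
    below ``threshold`` (the platform's evidence of expression)."""
    if detection_p.shape != matrix.shape:
        raise SchemaError(
            f"detection-p shape {detection_p.shape} != matrix shape {matrix.shape}"
        )
    dp = detection_p.reindex(index=matrix.feature_ids, columns=matrix.sample_ids)
    if dp.isna().any().any():
        raise SchemaError("detection-p ids do not match the matrix")
    keep = dp.mean(axis=1) < threshold
    return ExpressionMatrix(matrix.values.loc[keep], matrix.layer)


def log2_quantile_normalize(matrix: ExpressionMatrix, log_transform: bool = True) -> ExpressionMatrix:
    """log2-transform, then quantile normalize samples to a common
    distribution.

    The reference distribution is the across-sample mean of order
    statistics; each sample's sorted values are replaced by it. Tied
    values within a sample receive the mean of the reference values their
    ranks span (average-rank interpolation), so within-sample rank order
    is preserved and all samples end with identical value multisets when
    ties are absent.
    """
    x = matrix.to_numpy()
    if log_transform:
        if (x <= 0).any():
            g, s = np.argwhere(x <= 0)[0]
            raise ValueError(
                f"nonpositive value at feature {matrix.feature_ids[g]!r}, "
                f"sample {matrix.sample_ids[s]!r}: log2 undefined"
            )
        x = np.log2(x)
    n_g, n_s = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    ref = sorted_x.mean(axis=1)  # mean of order statistics
    # fractional (average) ranks per column, mapped onto the reference by
    # linear interpolation between adjacent order statistics
    out = np.empty_like(x)
    for j in range(n_s):
        assigned = np.empty(n_g)
        assigned[order[:, j]] = ref
        uniq, inv = np.unique(x[:, j], return_inverse=True)
        if len(uniq) < n_g:  # ties: average the spanned reference values
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.sample_ids),
        matrix.layer,
    )


def map_features(
    fmap: FeatureMap,
    serum: ExpressionMatrix,
    transcripts: ExpressionMatrix,
    collapse: str = "max_mean",
) -> pd.DataFrame:
    """Pair each serum protein with a transcript probe sharing its gene id.

    When several probes map to one gene the probe with the largest mean
    expression is chosen (``collapse="max_mean"``, the default and only
    rule currently implemented). Returns a DataFrame with columns
    ``protein_feature``, ``transcript_feature``, ``gene_id`` — one row per
    protein that has at least one measured transcript.
    """
    if collapse != "max_mean":
        raise ValueError(f"unknown probe-collapse rule {collapse!r}")
    prot_map = fmap.for_layer("serum").set_index("feature_id")["gene_id"]
    tr_map = fmap.for_layer(transcripts.layer)
    tr_map = tr_map[tr_map["feature_id"].isin(transcripts.feature_ids)]
    prot_map = prot_map[prot_map.index.isin(serum.feature_ids)]

    means = transcripts.values.mean(axis=1)
    tr_map = tr_map.assign(mean_expr=tr_map["feature_id"].map(means))
    best = (
        tr_map.sort_values(["gene_id", "mean_expr", "feature_id"], ascending=[True, False, True])
        .drop_duplicates("gene_id")
        .set_index("gene_id")["feature_id"]
    )
    rows = []
    for prot, gene in prot_map.items():
        if gene in best.index:
            rows.append((prot, best[gene], gene))
    return pd.DataFrame(rows, columns=["protein_feature", "transcript_feature", "gene_id"])
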