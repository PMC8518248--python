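"""Core in-memory containers shared by all analysis stages.

Expression data live in a features-by-samples :class:`pandas.DataFrame`
wrapped with a layer tag; subject metadata, feature maps and result tables
are plain DataFrames with documented schemas.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Recognized expression layers.
LAYERS = ("serum", "pbc", "skin")

#: Required columns of a subject table (indexed by subject id).
SUBJECT_COLUMNS = ("group", "age", "sex")

#: Group labels. "disease" plays the role of the patient arm, "control"
#: the unaffected arm.
GROUPS = ("disease", "control")


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass
class ExpressionMatrix:
    """A features × samples matrix of (log2-scale) expression values.

    Parameters
    ----------
    values
        DataFrame with unique feature ids as index and unique sample ids
        as columns. Samples are named by subject id (one sample per
        subject per layer).
    layer
        One of ``"serum"``, ``"pbc"``, ``"skin"``.
    """

    values: pd.DataFrame
    layer: str = "serum"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.layer not in LAYERS:
            raise SchemaError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups[:5]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[feature_ids], self.layer)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.layer)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def validate_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Check a subject table against the documented schema.

    The table is indexed by subject id and must carry ``group`` (one of
    ``disease``/``control``), ``age`` and ``sex`` columns; ``mrss`` is
    present for disease subjects and NaN for controls.
    """
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subject table missing column(s): {missing}")
    bad = set(subjects["group"].unique()) - set(GROUPS)
    if bad:
        raise SchemaError(f"unknown group label(s): {sorted(bad)}")
    if subjects.index.has_duplicates:
        raise SchemaError("duplicate subject ids")
    return subjects


@dataclass
class FeatureMap:
    """Feature-to-gene mapping across layers.

    ``table`` columns: ``feature_id``, ``gene_id``, ``layer``. A serum
    protein maps to at most one gene; several transcript probes may share
    a gene.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"feature_id", "gene_id", "layer"}
        missing = req - set(self.table.columns)
        if missing:
            raise SchemaError(f"feature map missing column(s): {sorted(missing)}")
        if (self.table["gene_id"].astype(str) == "").any():
            raise SchemaError("feature map has empty gene ids")
        serum = self.table[self.table["layer"] == "serum"]
        if serum["feature_id"].duplicated().any():
            raise SchemaError("a serum protein maps to more than one gene")

    def for_layer(self, layer: str) -> pd.DataFrame:
        return self.table[self.table["layer"] == layer].reset_index(drop=True)

    def genes(self, layer: str) -> pd.Index:
        return pd.Index(self.for_layer(layer)["gene_id"].unique())
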