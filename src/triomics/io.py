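"""TSV readers/writers for the pipeline's canonical on-disk formats.

All tables are tab-separated, UTF-8, '.' decimal. Matrices are written
features-in-rows with the sample ids as header; edge lists are two id
columns (plus an optional score column, as in STRING exports).
"""
from __future__ import annotations

import networkx as nx
import pandas as pd

from .containers import ExpressionMatrix, FeatureMap, SchemaError, validate_subjects


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.12g")


def read_matrix_tsv(path, layer: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate feature id {dup!r}")
    return ExpressionMatrix(df, layer)


def write_subjects_tsv(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index_label="subject_id")


def read_subjects_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_subjects(df)


def write_feature_map_tsv(fmap: FeatureMap, path) -> None:
    fmap.table.to_csv(path, sep="\t", index=False)


def read_feature_map_tsv(path) -> FeatureMap:
    return FeatureMap(pd.read_csv(path, sep="\t", dtype=str))


def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\n")
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


def read_edgelist_tsv(path, score_threshold: float | None = None) -> nx.Graph:
    """Read a STRING-style undirected edge list.

    The file has two id columns and optionally a third combined-score
    column; edges below ``score_threshold`` are dropped. Self-loops
    violate the simple-graph invariant and are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: edge list needs at least two columns")
    a, b = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    if score_threshold is not None and df.shape[1] >= 3:
        keep = df.iloc[:, 2].astype(float) >= score_threshold
        a, b = a[keep], b[keep]
    loops = a == b
    if loops.any():
        line = int(loops.idxmax()) + 2  # header is line 1
        raise SchemaError(f"{path}: self-loop at line {line}")
    g = nx.Graph()
    g.add_edges_from(zip(a, b))
    return g
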