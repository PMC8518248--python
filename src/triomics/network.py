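"""PPI-network scoring of differential expression.

Two statistics over an undirected simple protein-protein-interaction
graph: (i) WAP (Well-Associated Protein) scores — each node's sum of
neighbor differential-expression weights, ranked against a
weight-permutation null — and a degree-matched permutation comparison of
WAP ranks between two tissues; (ii) the observed count of edges between
two node sets tested against its expectation under the random graph with
given expected degrees (Chung-Lu null), with a Poisson tail p.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def _adjacency(graph: nx.Graph, nodes: list):
    import scipy.sparse as sp

    return nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")


def wap_scores(
    graph: nx.Graph,
    weights: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score every node by its attachment to highly weighted neighbors.

    S(v) = Σ_{u ∈ N(v)} w_u with w ≥ 0 (nodes absent from ``weights``
    get 0). The null permutes the weight vector over nodes ``n_perm``
    times; z = (S − mean_null)/sd_null and p is the upper-tail empirical
    probability with the add-one rule. Rank 1 is the most significant
    (ascending p, ties by descending z then node id).
    """
    nodes = sorted(graph.nodes())
    w = weights.reindex(nodes).fillna(0.0).to_numpy(float)
    if (w < 0).any():
        raise ValueError("WAP weights must be nonnegative")
    if not (w > 0).any():
        raise ValueError("all WAP weights are zero")
    a = _adjacency(graph, nodes)
    s_obs = a @ w
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(nodes)))
    for i in range(n_perm):
        null[i] = a @ rng.permutation(w)
    mean_null = null.mean(axis=0)
    sd_null = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (s_obs - mean_null) / sd_null
    z = np.where(np.isfinite(z), z, 0.0)
    p = (1 + (null >= s_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    out = pd.DataFrame(
        {"score": s_obs, "null_mean": mean_null, "null_sd": sd_null, "z": z, "p": p},
        index=pd.Index(nodes, name="node"),
    )
    order = out.sort_values(["p", "z"], ascending=[True, False], kind="stable")
    # deterministic tie-break: p asc, z desc, node id asc (index sort is
    # stable after the sort above because sorted(nodes) fixed base order)
    out["rank"] = pd.Series(np.arange(1, len(out) + 1), index=order.index)
    return out


def compare_wap_ranks(
    wap_a: pd.DataFrame,
    wap_b: pd.DataFrame,
    protein_set,
    graph: nx.Graph,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Median WAP-rank shift of a protein set between two tissues.

    Statistic = median over the set of (rank_b − rank_a); positive means
    the set is ranked more prominently (smaller ranks) in tissue a. The
    null draws ``n_perm`` random node sets of the same size matched on
    degree decile, so connectedness is compared at like-for-like degree.
    Upper-tail p with the add-one rule.
    """
    protein_set = [p for p in protein_set]
    common = wap_a.index.intersection(wap_b.index)
    # zero-degree nodes carry no attachment signal and sit at identical
    # tied ranks in both tissues; they would put an atom at zero rank
    # difference, so the comparison universe is connected nodes only
    deg_all = dict(graph.degree())
    common = common[[deg_all.get(n, 0) > 0 for n in common]]
    missing = [p for p in protein_set if p not in common]
    if missing:
        raise ValueError(
            f"protein set members not scored in both tissues or isolated: {missing[:5]}"
        )
    if len(protein_set) < 5:
        raise ValueError("protein set must have at least 5 members")
    stat = float(np.median(wap_b.loc[protein_set, "rank"] - wap_a.loc[protein_set, "rank"]))

    degrees = pd.Series({n: d for n, d in graph.degree()}).reindex(common).fillna(0)
    deciles = pd.qcut(degrees.rank(method="first"), 10, labels=False, duplicates="drop")
    in_set = deciles.index.isin(protein_set)
    by_decile = {}
    for d in np.unique(deciles):
        members = deciles.index[(deciles == d) & ~in_set].to_numpy()
        if len(members) == 0:  # degenerate decile made only of query nodes
            members = deciles.index[deciles == d].to_numpy()
        by_decile[d] = members
    set_deciles = deciles.loc[protein_set].to_numpy()

    rng = np.random.default_rng(seed)
    diffs = (wap_b["rank"] - wap_a["rank"]).reindex(common)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = [rng.choice(by_decile[d]) for d in set_deciles]
        null[i] = np.median(diffs.loc[draw])
    p = (1 + (null >= stat).sum()) / (n_perm + 1)
    return {"statistic": stat, "p": float(p), "null": null, "n_set": len(protein_set)}


def _cross_pair_arrays(graph: nx.Graph, set_a, set_b):
    set_a = list(dict.fromkeys(set_a))
    set_b = list(dict.fromkeys(set_b))
    if not set_a or not set_b:
        raise ValueError("node sets must be nonempty")
    unknown = [v for v in set_a + set_b if v not in graph]
    if unknown:
        raise ValueError(f"nodes not in graph: {unknown[:5]}")
    return set_a, set_b


def expected_edge_count(graph: nx.Graph, set_a, set_b) -> float:
    """Expected cross-edges under the expected-degrees (Chung-Lu) null.

    e_exp = Σ over unordered qualifying pairs {a, b} (a ∈ A, b ∈ B,
    a ≠ b, each pair counted once even when both nodes lie in A ∩ B) of
    min(1, d_a·d_b / 2m), with d the observed degrees and m the edge
    count of the graph itself.
    """
    set_a, set_b = _cross_pair_arrays(graph, set_a, set_b)
    two_m = 2 * graph.number_of_edges()
    if two_m == 0:
        raise ValueError("graph has no edges")
    return expected_edge_count_from_degrees(dict(graph.degree()), two_m, set_a, set_b)


def expected_edge_count_from_degrees(deg: dict, two_m: float, set_a, set_b) -> float:
    """Expected-degrees cross-edge expectation from a degree map.

    Same unordered-pair rule as :func:`expected_edge_count`; useful when
    the expected degrees are known analytically rather than observed on a
    sampled graph."""
    set_a = list(dict.fromkeys(set_a))
    set_b = list(dict.fromkeys(set_b))
    da = np.array([deg[v] for v in set_a], float)
    db = np.array([deg[v] for v in set_b], float)
    pmat = np.minimum(1.0, np.outer(da, db) / two_m)
    ia = {v: i for i, v in enumerate(set_a)}
    ib = {v: i for i, v in enumerate(set_b)}
    same = [(ia[v], ib[v]) for v in set_a if v in ib]
    ordered = pmat.sum() - sum(pmat[i, j] for i, j in same)  # drop a == b terms
    inter = [v for v in set_a if v in ib]
    s_ii = 0.0
    for x in inter:  # ordered sum over distinct intersection pairs
        for y in inter:
            if x != y:
                s_ii += min(1.0, deg[x] * deg[y] / two_m)
    return float(ordered - 0.5 * s_ii)


def observed_edge_count(graph: nx.Graph, set_a, set_b) -> int:
    """Observed cross-edges by the same unordered-pair rule."""
    set_a, set_b = _cross_pair_arrays(graph, set_a, set_b)
    sa, sb = set(set_a), set(set_b)
    count = 0
    for u, v in graph.edges():
        if (u in sa and v in sb) or (v in sa and u in sb):
            count += 1
    return count


@dataclass
class EdgeCountResult:
    set_a: list
    set_b: list
    e_obs: int
    e_exp: float
    ratio: float
    p: float


def edge_count_test(graph: nx.Graph, set_a, set_b) -> EdgeCountResult:
    """Poisson tail test of cross-edge enrichment.

    p = P(X ≥ e_obs) for X ~ Poisson(λ = e_exp); ratio = e_obs / e_exp
    (ratio 1 is the unremarkable case of observing exactly the expected
    count).
    """
    e_exp = expected_edge_count(graph, set_a, set_b)
    if e_exp <= 0:
        raise ValueError("expected edge count is zero; test undefined")
    e_obs = observed_edge_count(graph, set_a, set_b)
    p = float(stats.poisson.sf(e_obs - 1, e_exp))
    return EdgeCountResult(
        set_a=list(set_a), set_b=list(set_b), e_obs=e_obs, e_exp=e_exp,
        ratio=e_obs / e_exp, p=p,
    )


def top_k_de_nodes(de: pd.DataFrame, fmap, layer: str, k: int) -> list:
    """Map the k most differentially expressed features to network nodes.

    Features sort by ascending p, ties by descending |t| then feature id;
    the top k are mapped to gene ids and duplicates collapsed (order
    preserved).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(de):
        raise ValueError(f"k={k} exceeds the {len(de)} available features")
    ranked = de.assign(abs_t=de["t"].abs()).sort_values(
        ["p", "abs_t"], ascending=[True, False], kind="stable"
    )
    top = ranked.index[:k]
    gene_of = fmap.for_layer(layer).set_index("feature_id")["gene_id"]
    genes = [gene_of[f] for f in top if f in gene_of.index]
    return list(dict.fromkeys(genes))
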