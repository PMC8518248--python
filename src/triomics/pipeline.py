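"""End-to-end orchestration: simulate (or load) → preprocess → differential
expression → trait association → cross-layer → network → concordance.

Every stage draws its randomness from a seed derived deterministically
from the master seed by stage position, so reruns with the same
configuration are byte-identical and adding a stage never perturbs the
streams of earlier ones.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .concordance import pairwise_concordance
from .crosslayer import (
    disease_vs_trait_concordance,
    per_gene_cross_tissue_correlation,
    permutation_effect_correlation,
)
from .de import fit_group_de, trait_association
from .network import compare_wap_ranks, edge_count_test, top_k_de_nodes, wap_scores
from .preprocess import (
    filter_by_detection,
    filter_by_llod,
    impute_llod,
    log2_quantile_normalize,
    map_features,
)
from .simulate import SyntheticConfig, generate_cohort, generate_multiomic, generate_ppi_network

#: Stage order; each stage's seed is the master SeedSequence word at its
#: fixed position, so the list may only ever be appended to.
STAGES = ("simulate", "network_build", "de", "trait", "crosslayer", "network", "concordance")


class ValidationError(ValueError):
    """Raised when a run configuration is out of range."""


@dataclass
class RunConfig:
    """Pipeline settings: thresholds, permutation counts, seed, output."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    covariates: tuple = ("age", "sex")
    detection_threshold: float = 0.01
    max_below_llod: float = 0.5
    fdr_threshold: float = 0.05
    selection_rule: str = "p:0.05"
    n_perm_crosslayer: int = 199
    n_perm_network: int = 199
    n_perm_concordance: int = 999
    top_k_edges: tuple = (50, 100, 250)
    log_transform: bool = False  # synthetic values are already log2-scale
    planted_excess_p: float = 0.01
    moderate: bool = True
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        if not 0 < self.detection_threshold <= 1:
            raise ValidationError(f"detection_threshold out of (0, 1]: {self.detection_threshold}")
        if not 0 <= self.max_below_llod < 1:
            raise ValidationError(f"max_below_llod out of [0, 1): {self.max_below_llod}")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError(f"fdr_threshold out of (0, 1): {self.fdr_threshold}")
        for name in ("n_perm_crosslayer", "n_perm_network", "n_perm_concordance"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        self.synthetic.validate()
        return self


def stage_seeds(master: int) -> dict[str, int]:
    words = np.random.SeedSequence(master).generate_state(len(STAGES))
    return {name: int(words[i]) for i, name in enumerate(STAGES)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-mode pipeline; returns the result bundle.

    When ``config.out_dir`` is set, all tables are written as TSV plus a
    machine-readable ``results.json`` and a ``run_log.json`` echoing the
    parameters and per-stage seeds.
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    bundle: dict = {"seed": config.seed, "stage_seeds": seeds}

    # --- simulate -------------------------------------------------------
    syn = SyntheticConfig(**{**asdict(config.synthetic), "seed": seeds["simulate"]})
    subjects = generate_cohort(syn)
    serum_raw, llod, pbc_raw, pbc_det, skin_raw, skin_det, fmap, truth = generate_multiomic(
        subjects, syn
    )

    # --- preprocess -----------------------------------------------------
    groups = subjects["group"]
    serum_kept, llod_report = filter_by_llod(
        serum_raw, llod, groups.reindex(serum_raw.sample_ids), config.max_below_llod
    )
    serum_imp = impute_llod(serum_kept, llod)
    serum = log2_quantile_normalize(serum_imp, log_transform=config.log_transform)
    pbc = log2_quantile_normalize(
        filter_by_detection(pbc_raw, pbc_det, config.detection_threshold),
        log_transform=config.log_transform,
    )
    skin = log2_quantile_normalize(
        filter_by_detection(skin_raw, skin_det, config.detection_threshold),
        log_transform=config.log_transform,
    )
    pairs_pbc = map_features(fmap, serum, pbc)
    pairs_skin = map_features(fmap, serum, skin)

    # --- network build --------------------------------------------------
    genes = sorted(fmap.table["gene_id"].unique())
    gene_of = fmap.table.set_index("feature_id")["gene_id"]
    planted = None
    if config.planted_excess_p > 0:
        set_a = sorted({gene_of[f] for f in truth.de_features["serum"]})
        set_b = sorted({gene_of[f] for f in truth.de_features["skin"]})
        planted = (set_a, set_b, config.planted_excess_p)
        truth.planted_module = {"serum_genes": set_a, "skin_genes": set_b}
    graph = generate_ppi_network(
        len(genes), node_labels=genes, planted_module=planted, seed=seeds["network_build"]
    )

    # --- differential expression ---------------------------------------
    de = {
        "serum": fit_group_de(serum, subjects, config.covariates, config.moderate),
        "pbc": fit_group_de(pbc, subjects, config.covariates, config.moderate),
        "skin": fit_group_de(skin, subjects, config.covariates, config.moderate),
    }
    trait = trait_association(serum, subjects, covariates=config.covariates)

    # --- cross-layer ----------------------------------------------------
    cross = {}
    for layer, mat, pairs in (("skin", skin, pairs_skin), ("pbc", pbc, pairs_pbc)):
        res = permutation_effect_correlation(
            serum, mat, subjects, pairs,
            selection=config.selection_rule, covariates=config.covariates,
            moderate=config.moderate, n_perm=config.n_perm_crosslayer,
            seed=seeds["crosslayer"],
        )
        cross[layer] = {"rho": res.rho_obs, "p": res.p_perm, "n_pairs": res.n_pairs}
    conc = disease_vs_trait_concordance(de["serum"], trait, cutoff=config.fdr_threshold)
    gene_corr = per_gene_cross_tissue_correlation(skin, pbc, fmap, subjects)

    # --- network statistics --------------------------------------------
    def gene_weights(de_tbl, layer):
        gm = fmap.for_layer(layer).set_index("feature_id")["gene_id"]
        w = de_tbl["t"].abs()
        w.index = w.index.map(gm)
        return w.groupby(level=0).max()

    wap = {
        layer: wap_scores(graph, gene_weights(de[layer], layer),
                          n_perm=config.n_perm_network, seed=seeds["network"])
        for layer in ("pbc", "skin")
    }
    deg = dict(graph.degree())
    serum_de_genes = sorted(
        g for g in {gene_of[f] for f in de["serum"].index[de["serum"]["fdr"] < config.fdr_threshold]}
        if deg.get(g, 0) > 0
    )
    wap_cmp = None
    if len(serum_de_genes) >= 5:
        # positive statistic: serum proteins sit closer to skin perturbation
        wap_cmp = compare_wap_ranks(
            wap["skin"], wap["pbc"], serum_de_genes, graph,
            n_perm=config.n_perm_network, seed=seeds["network"],
        )
        wap_cmp = {k: wap_cmp[k] for k in ("statistic", "p", "n_set")}
    edge_tests = {}
    for layer in ("pbc", "skin"):
        for k in config.top_k_edges:
            kk = min(k, len(de[layer]))
            top_nodes = top_k_de_nodes(de[layer], fmap, layer, kk)
            if serum_de_genes and top_nodes:
                r = edge_count_test(graph, serum_de_genes, top_nodes)
                edge_tests[f"{layer}_top{k}"] = {
                    "e_obs": r.e_obs, "e_exp": r.e_exp, "ratio": r.ratio, "p": r.p
                }

    # --- concordance ----------------------------------------------------
    grid = pairwise_concordance(
        {"serum": serum, "pbc": pbc, "skin": skin}, subjects,
        n_perm=config.n_perm_concordance, seed=seeds["concordance"],
    )

    bundle.update(
        subjects=subjects, matrices={"serum": serum, "pbc": pbc, "skin": skin},
        llod_report=llod_report, feature_map=fmap, truth=truth, graph=graph,
        de=de, trait=trait, cross_layer=cross,
        disease_trait_concordance={
            "n_tested": conc.n_tested, "n_concordant": conc.n_concordant, "rho": conc.rho
        },
        gene_cross_tissue=gene_corr, wap=wap, wap_rank_comparison=wap_cmp,
        edge_count=edge_tests, mantel_grid=grid,
    )
    if config.out_dir is not None:
        _write_bundle(config, bundle)
    return bundle


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    return x


def _write_bundle(config: RunConfig, bundle: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_subjects_tsv(bundle["subjects"], out / "subjects.tsv")
    for layer, mat in bundle["matrices"].items():
        tio.write_matrix_tsv(mat, out / f"{layer}_normalized.tsv")
    tio.write_feature_map_tsv(bundle["feature_map"], out / "feature_map.tsv")
    tio.write_edgelist_tsv(bundle["graph"], out / "ppi_edges.tsv")
    for layer, tbl in bundle["de"].items():
        tbl.to_csv(out / f"de_{layer}.tsv", sep="\t", index_label="feature_id")
    bundle["trait"].to_csv(out / "trait_association.tsv", sep="\t", index_label="feature_id")
    bundle["gene_cross_tissue"].to_csv(out / "gene_cross_tissue.tsv", sep="\t", index=False)
    bundle["mantel_grid"].to_csv(out / "mantel_grid.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle["truth"].to_jsonable(), fh, indent=1, sort_keys=True, default=_jsonable)
    results = {
        "seed": bundle["seed"],
        "cross_layer": bundle["cross_layer"],
        "disease_trait_concordance": bundle["disease_trait_concordance"],
        "wap_rank_comparison": bundle["wap_rank_comparison"],
        "edge_count": bundle["edge_count"],
        "mantel_grid": bundle["mantel_grid"].to_dict(orient="records"),
        "n_de": {
            layer: int((tbl["fdr"] < config.fdr_threshold).sum())
            for layer, tbl in bundle["de"].items()
        },
        "n_proteins_retained": int(bundle["matrices"]["serum"].shape[0]),
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_jsonable)
    log = {
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "synthetic"},
            "synthetic": asdict(config.synthetic),
        },
        "stage_seeds": bundle["stage_seeds"],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True, default=_jsonable)
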