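"""Coupled three-layer synthetic omics generator with known planted truth.

Emulates a two-arm cross-sectional cohort profiled on three molecular
layers — a serum protein panel with a lower limit of detection (LLOD),
and two transcriptome layers (peripheral blood cells and skin) with
platform detection p-values — plus a protein-protein-interaction network.
Group differences, a clinical-trait loading, cross-layer effect coupling
and a shared per-subject latent factor are all planted and recorded so
every downstream stage has a recoverable ground truth.

Value model per layer (log2 scale), feature g, sample i::

    x_gi = baseline_g + effect_g * 1[i diseased]
           + latent_strength * u_g * l_i        (shared latent factor l_i)
           + trait_slope_g * mRSS_i             (serum trait features)
           + noise,   noise ~ N(0, noise_sd)

The per-layer loading vectors ``u_g`` are independent standard normals;
because the latent factor ``l_i`` is shared across layers it induces
concordant between-sample similarity structure, which is what the Mantel
stage recovers. Cross-layer coupling is planted on mapped
protein↔transcript pairs where both members carry a group effect:
``e_t = rho * e_s + sqrt(1 - rho^2) * eps`` with ``eps ~ N(0, effect_sd)``,
so the planted mapped-pair effect correlation is ``rho`` in expectation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FeatureMap, validate_subjects


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the study cohort's dimensions.

    Two arms (49 disease / 25 control, serum missing for 2 disease and 1
    control subject), a 981-protein serum panel of which 70 analytes are
    heavily left-censored, and two transcript layers whose gene maps cover
    314/448 of the retained proteins respectively.
    """

    n_disease: int = 49
    n_control: int = 25
    n_serum_dropout_disease: int = 2
    n_serum_dropout_control: int = 1
    n_proteins: int = 981
    n_censored_proteins: int = 70
    n_transcripts_pbc: int = 1500
    n_transcripts_skin: int = 1500
    frac_mapped_pbc: float = 314 / 911
    frac_mapped_skin: float = 448 / 911
    n_de_serum: int = 70
    n_de_pbc: int = 78
    n_de_skin: int = 150
    effect_sd: float = 0.8
    coupling_rho_skin: float = 0.6
    coupling_rho_pbc: float = 0.2
    latent_strength_serum: float = 0.15
    latent_strength_pbc: float = 0.15
    latent_strength_skin: float = 0.15
    noise_sd: float = 1.0
    llod_quantile: float = 0.05
    mrss_effect: float = 0.05
    frac_unexpressed: float = 0.10
    feature_block_rho: float = 0.0
    latent_disease_only: bool = False
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        counts = dict(
            n_disease=self.n_disease,
            n_control=self.n_control,
            n_serum_dropout_disease=self.n_serum_dropout_disease,
            n_serum_dropout_control=self.n_serum_dropout_control,
            n_proteins=self.n_proteins,
            n_censored_proteins=self.n_censored_proteins,
            n_transcripts_pbc=self.n_transcripts_pbc,
            n_transcripts_skin=self.n_transcripts_skin,
            n_de_serum=self.n_de_serum,
            n_de_pbc=self.n_de_pbc,
            n_de_skin=self.n_de_skin,
        )
        for name, v in counts.items():
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v}")
        if self.n_censored_proteins > self.n_proteins:
            raise ConfigurationError("n_censored_proteins exceeds n_proteins")
        if self.n_de_pbc > self.n_transcripts_pbc:
            raise ConfigurationError("n_de_pbc exceeds n_transcripts_pbc")
        if self.n_de_skin > self.n_transcripts_skin:
            raise ConfigurationError("n_de_skin exceeds n_transcripts_skin")
        for name in ("coupling_rho_skin", "coupling_rho_pbc"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [-1, 1], got {v}")
        for name in ("frac_mapped_pbc", "frac_mapped_skin", "llod_quantile", "frac_unexpressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0 or self.effect_sd < 0:
            raise ConfigurationError("effect_sd and noise_sd must be nonnegative")
        return self


@dataclass
class SyntheticTruth:
    """Planted structure recorded by the generator."""

    de_features: dict[str, list[str]]
    effects: dict[str, pd.Series]
    trait_slopes: pd.Series
    realized_coupling: dict[str, float]
    latent: pd.Series
    censored_proteins: list[str]
    planted_module: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "de_features": self.de_features,
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "trait_slopes": self.trait_slopes.to_dict(),
            "realized_coupling": self.realized_coupling,
            "latent": self.latent.to_dict(),
            "censored_proteins": list(self.censored_proteins),
            "planted_module": self.planted_module,
            "seed": self.seed,
        }


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the clinical table: group, age, sex, mRSS, subtype, antibodies.

    Disease-arm ages are N(52, 14), controls N(46, 12); the female fraction
    is 71% in the disease arm and 84% in controls. mRSS (a 0-51 skin score)
    is present for disease subjects only, drawn as round(51·Beta(1.2, 3))
    to match its support and right skew; subtype and antibody flags are
    independent Bernoulli draws at the cohort frequencies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_d, n_c = config.n_disease, config.n_control
    n = n_d + n_c
    ids = [f"S{i + 1:03d}" for i in range(n)]
    group = np.array(["disease"] * n_d + ["control"] * n_c)
    age = np.where(
        group == "disease",
        rng.normal(52.0, 14.0, n),
        rng.normal(46.0, 12.0, n),
    ).round(1)
    p_female = np.where(group == "disease", 35 / 49, 21 / 25)
    sex = np.where(rng.random(n) < p_female, "F", "M")
    mrss = np.full(n, np.nan)
    mrss[:n_d] = np.round(51.0 * rng.beta(1.2, 3.0, n_d))
    subtype = np.array(["" for _ in range(n)], dtype=object)
    subtype[:n_d] = np.where(rng.random(n_d) < 32 / 49, "diffuse", "limited")
    subtype[n_d:] = "none"
    tbl = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "mrss": mrss,
            "subtype": subtype,
            "anti_centromere": (rng.random(n) < 7 / 49) & (group == "disease"),
            "anti_topoisomerase": (rng.random(n) < 13 / 49) & (group == "disease"),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    return validate_subjects(tbl)


def _layer_matrix(
    rng: np.random.Generator,
    feature_ids: list[str],
    subjects: pd.DataFrame,
    effects: pd.Series,
    latent: pd.Series,
    latent_strength: float,
    noise_sd: float,
    trait_slopes: pd.Series | None = None,
    block_rho: float = 0.0,
) -> pd.DataFrame:
    n_g, n_s = len(feature_ids), len(subjects)
    baseline = rng.normal(8.0, 1.0, n_g)
    loadings = rng.normal(0.0, 1.0, n_g)
    disease = (subjects["group"] == "disease").to_numpy(float)
    x = baseline[:, None] + np.outer(effects.to_numpy(), disease)
    x += latent_strength * np.outer(loadings, latent.to_numpy())
    if trait_slopes is not None:
        mrss = subjects["mrss"].fillna(0.0).to_numpy()
        x += np.outer(trait_slopes.to_numpy(), mrss)
    noise = rng.normal(0.0, noise_sd, (n_g, n_s))
    if block_rho > 0:
        # optional shared-noise component inducing feature-block correlation
        shared = rng.normal(0.0, noise_sd, n_s)
        noise = np.sqrt(1 - block_rho) * noise + np.sqrt(block_rho) * shared[None, :]
    x += noise
    return pd.DataFrame(x, index=feature_ids, columns=subjects.index)


def generate_multiomic(subjects: pd.DataFrame, config: SyntheticConfig):
    """Generate the three coupled expression layers plus map and truth.

    Returns
    -------
    tuple
        ``(serum, llod, pbc, pbc_detection, skin, skin_detection, fmap,
        truth)`` where ``serum``/``pbc``/``skin`` are
        :class:`ExpressionMatrix`, ``llod`` is a per-protein Series,
        the detection tables are probe × sample DataFrames, ``fmap`` a
        :class:`FeatureMap` and ``truth`` a :class:`SyntheticTruth`.

    Serum values are left uncensored here; the preprocessing stage
    replaces sub-LLOD observations by the LLOD, mirroring how panel data
    arrive with extrapolated below-detection values. The ``llod`` vector
    is placed at the ``llod_quantile`` of each protein's control
    distribution, except for the ``n_censored_proteins`` designated
    analytes whose LLOD sits above their 55th overall percentile so that
    strictly more than half of their observations fall below it.
    """
    if len(subjects) == 0:
        raise ConfigurationError("subject table is empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    prot_ids = [f"PROT{i + 1:04d}" for i in range(config.n_proteins)]
    prot_genes = {p: f"GENE{i + 1:05d}" for i, p in enumerate(prot_ids)}

    censored = list(rng.choice(prot_ids, size=config.n_censored_proteins, replace=False))
    uncensored = [p for p in prot_ids if p not in set(censored)]

    # gene maps: mapped proteins are drawn from the analytes that survive
    # the censoring filter, so the pairing counts downstream match
    # frac_mapped_* of the retained panel
    maps = {}
    for layer, frac, n_tr in (
        ("pbc", config.frac_mapped_pbc, config.n_transcripts_pbc),
        ("skin", config.frac_mapped_skin, config.n_transcripts_skin),
    ):
        n_mapped = min(int(round(frac * len(uncensored))), n_tr, len(uncensored))
        mapped_prots = list(rng.choice(uncensored, size=n_mapped, replace=False))
        tr_ids = [f"T{layer.upper()}{i + 1:05d}" for i in range(n_tr)]
        gene_of_tr = {}
        for i, p in enumerate(mapped_prots):
            gene_of_tr[tr_ids[i]] = prot_genes[p]
        extra_gene_start = config.n_proteins + 1
        for j, t in enumerate(tr_ids[n_mapped:]):
            gene_of_tr[t] = f"GENE{extra_gene_start + j + (0 if layer == 'pbc' else n_tr):05d}"
        maps[layer] = (mapped_prots, tr_ids, gene_of_tr)

    # planted serum effects
    n_de_serum = min(config.n_de_serum, len(uncensored))
    de_serum = list(rng.choice(uncensored, size=n_de_serum, replace=False))
    eff_serum = pd.Series(0.0, index=prot_ids)
    eff_serum[de_serum] = rng.normal(0.0, config.effect_sd, n_de_serum)

    # transcript effects: pair-planted transcripts get coupled effects
    effects = {"serum": eff_serum}
    de_features = {"serum": de_serum}
    realized = {}
    for layer, rho, n_de in (
        ("pbc", config.coupling_rho_pbc, config.n_de_pbc),
        ("skin", config.coupling_rho_skin, config.n_de_skin),
    ):
        mapped_prots, tr_ids, gene_of_tr = maps[layer]
        tr_of_prot = {p: tr_ids[i] for i, p in enumerate(mapped_prots)}
        paired_prots = [p for p in de_serum if p in tr_of_prot]
        if rho != 0.0 and n_de > 0 and len(paired_prots) < 3:
            raise ConfigurationError(
                f"coupling_rho_{layer}={rho} infeasible: only {len(paired_prots)} "
                "planted serum proteins map to this layer (need >= 3); increase "
                "n_de_serum or frac_mapped"
            )
        paired_tr = [tr_of_prot[p] for p in paired_prots][:n_de]
        n_rest = n_de - len(paired_tr)
        rest_pool = [t for t in tr_ids if t not in set(paired_tr)]
        rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
        de_layer = paired_tr + rest
        eff = pd.Series(0.0, index=tr_ids)
        if paired_tr:
            e_s = eff_serum[paired_prots[: len(paired_tr)]].to_numpy()
            eps = rng.normal(0.0, config.effect_sd, len(paired_tr))
            eff[paired_tr] = rho * e_s + np.sqrt(max(0.0, 1 - rho**2)) * eps
        if rest:
            eff[rest] = rng.normal(0.0, config.effect_sd, len(rest))
        effects[layer] = eff
        de_features[layer] = de_layer
        if len(paired_tr) >= 2:
            e_s = eff_serum[paired_prots[: len(paired_tr)]].to_numpy()
            realized[layer] = float(np.corrcoef(e_s, eff[paired_tr].to_numpy())[0, 1])
        else:
            realized[layer] = float("nan")

    # trait loadings on the planted serum features, signed with the group
    # effect so disease-upregulated proteins also track severity
    trait_slopes = pd.Series(0.0, index=prot_ids)
    trait_slopes[de_serum] = config.mrss_effect * np.sign(eff_serum[de_serum]) * (
        0.5 + np.abs(eff_serum[de_serum]) / max(config.effect_sd, 1e-12)
    )

    latent = pd.Series(rng.normal(0.0, 1.0, len(subjects)), index=subjects.index)
    if config.latent_disease_only:
        latent[subjects["group"] != "disease"] = 0.0

    # serum availability: a few subjects per arm lack a serum sample
    d_ids = subjects.index[subjects["group"] == "disease"]
    c_ids = subjects.index[subjects["group"] == "control"]
    drop = []
    if config.n_serum_dropout_disease and len(d_ids):
        drop += list(rng.choice(d_ids, size=min(config.n_serum_dropout_disease, len(d_ids)), replace=False))
    if config.n_serum_dropout_control and len(c_ids):
        drop += list(rng.choice(c_ids, size=min(config.n_serum_dropout_control, len(c_ids)), replace=False))
    serum_subjects = subjects.drop(index=drop)

    serum_vals = _layer_matrix(
        rng, prot_ids, serum_subjects, eff_serum, latent[serum_subjects.index],
        config.latent_strength_serum, config.noise_sd,
        trait_slopes=trait_slopes, block_rho=config.feature_block_rho,
    )
    pbc_vals = _layer_matrix(
        rng, maps["pbc"][1], subjects, effects["pbc"], latent,
        config.latent_strength_pbc, config.noise_sd, block_rho=config.feature_block_rho,
    )
    skin_vals = _layer_matrix(
        rng, maps["skin"][1], subjects, effects["skin"], latent,
        config.latent_strength_skin, config.noise_sd, block_rho=config.feature_block_rho,
    )

    # per-protein LLOD
    ctrl_cols = serum_subjects.index[serum_subjects["group"] == "control"]
    llod = serum_vals[ctrl_cols].quantile(config.llod_quantile, axis=1) if len(ctrl_cols) else serum_vals.quantile(config.llod_quantile, axis=1)
    # cap ordinary LLODs at the 40th overall percentile so large planted
    # down-shifts can never push a non-designated analyte past the >50%
    # exclusion threshold; designated analytes sit above their median
    llod = np.minimum(llod, serum_vals.quantile(0.40, axis=1))
    heavy = serum_vals.loc[censored].quantile(0.55, axis=1)
    llod = llod.copy()
    llod[censored] = heavy
    below = serum_vals.lt(llod, axis=0).mean(axis=1)
    assert (below[censored] > 0.5).all(), "forced-censoring construction failed"

    # detection p-values: expressed probes near zero, a fraction of
    # unplanted/unmapped probes drawn above the filter threshold
    detection = {}
    for layer in ("pbc", "skin"):
        mapped_prots, tr_ids, gene_of_tr = maps[layer]
        n_mapped = len(mapped_prots)
        protected = set(tr_ids[:n_mapped]) | set(de_features[layer])
        pool = [t for t in tr_ids if t not in protected]
        n_unexpr = min(int(round(config.frac_unexpressed * len(tr_ids))), len(pool))
        unexpr = set(rng.choice(pool, size=n_unexpr, replace=False)) if n_unexpr else set()
        n_s = len(subjects)
        dp = pd.DataFrame(
            rng.uniform(0.0, 0.005, (len(tr_ids), n_s)), index=tr_ids, columns=subjects.index
        )
        if unexpr:
            dp.loc[list(unexpr)] = rng.uniform(0.01, 1.0, (len(unexpr), n_s))
        detection[layer] = dp

    rows = [(p, prot_genes[p], "serum") for p in prot_ids]
    for layer in ("pbc", "skin"):
        _, tr_ids, gene_of_tr = maps[layer]
        rows += [(t, gene_of_tr[t], layer) for t in tr_ids]
    fmap = FeatureMap(pd.DataFrame(rows, columns=["feature_id", "gene_id", "layer"]))

    truth = SyntheticTruth(
        de_features=de_features,
        effects=effects,
        trait_slopes=trait_slopes,
        realized_coupling=realized,
        latent=latent,
        censored_proteins=censored,
        seed=config.seed,
    )
    serum = ExpressionMatrix(serum_vals, "serum")
    pbc = ExpressionMatrix(pbc_vals, "pbc")
    skin = ExpressionMatrix(skin_vals, "skin")
    return serum, llod, pbc, detection["pbc"], skin, detection["skin"], fmap, truth


def powerlaw_expected_degrees(
    n_nodes: int, exponent: float = 2.5, min_degree: int = 1, rng=None
) -> np.ndarray:
    """Draw expected degrees from a truncated discrete power law.

    P(k) ∝ k^(−exponent) on [min_degree, n_nodes − 1]."""
    rng = np.random.default_rng(rng)
    ks = np.arange(min_degree, n_nodes)
    pk = ks.astype(float) ** (-exponent)
    pk /= pk.sum()
    return rng.choice(ks, size=n_nodes, p=pk).astype(float)


def generate_ppi_network(
    n_nodes: int,
    expected_degrees: np.ndarray | None = None,
    exponent: float = 2.5,
    planted_module: tuple | None = None,
    node_labels: list[str] | None = None,
    seed: int | None = None,
) -> nx.Graph:
    """Sample an undirected simple graph from the expected-degrees model.

    Edge probability between nodes i and j is ``min(1, w_i w_j / sum(w))``
    — the Chung-Lu model, the same null the edge-count test assumes, so
    downstream calibration is exact by construction. ``planted_module``
    is ``(set_a, set_b, excess_p)``: every cross pair between the two
    designated label sets has ``excess_p`` added to its edge probability.
    """
    if n_nodes < 2:
        raise ConfigurationError("n_nodes must be at least 2")
    rng = np.random.default_rng(seed)
    if expected_degrees is None:
        w = powerlaw_expected_degrees(n_nodes, exponent=exponent, rng=rng)
    else:
        w = np.asarray(expected_degrees, dtype=float)
        if len(w) != n_nodes:
            raise ConfigurationError("expected_degrees length must equal n_nodes")
        if (w < 0).any() or w.max() > n_nodes - 1:
            raise ConfigurationError(
                f"requested expected degrees unrealizable: max {w.max()} exceeds n_nodes-1={n_nodes - 1}"
            )
    labels = node_labels if node_labels is not None else [f"G{i + 1:05d}" for i in range(n_nodes)]
    if len(labels) != n_nodes:
        raise ConfigurationError("node_labels length must equal n_nodes")

    s = w.sum()
    iu, ju = np.triu_indices(n_nodes, k=1)
    p = np.minimum(1.0, w[iu] * w[ju] / s) if s > 0 else np.zeros(len(iu))
    if planted_module is not None:
        set_a, set_b, excess = planted_module
        idx = {lab: i for i, lab in enumerate(labels)}
        in_a = np.zeros(n_nodes, bool)
        in_b = np.zeros(n_nodes, bool)
        in_a[[idx[x] for x in set_a if x in idx]] = True
        in_b[[idx[x] for x in set_b if x in idx]] = True
        cross = (in_a[iu] & in_b[ju]) | (in_b[iu] & in_a[ju])
        p = np.where(cross, np.minimum(1.0, p + excess), p)
    draw = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from(
        (labels[i], labels[j]) for i, j in zip(iu[draw], ju[draw])
    )
    return g
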