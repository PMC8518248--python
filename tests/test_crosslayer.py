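"""Cross-layer effect correlations and their permutation nulls."""
import numpy as np
import pandas as pd
import pytest

from triomics.crosslayer import (
    disease_vs_trait_concordance,
    effect_correlation,
    per_gene_cross_tissue_correlation,
    permutation_effect_correlation,
)
from triomics.containers import ExpressionMatrix, FeatureMap
from triomics.de import fit_group_de, trait_association
from triomics.preprocess import map_features
from conftest import make_matrix


def _de_table(effects, pvals=None):
    effects = np.asarray(effects, float)
    p = np.asarray(pvals, float) if pvals is not None else np.full(len(effects), 0.01)
    return pd.DataFrame(
        {"effect": effects, "p": p, "fdr": p, "t": effects},
        index=[f"F{i}" for i in range(len(effects))],
    )


def _pairs(n):
    return pd.DataFrame(
        {
            "protein_feature": [f"F{i}" for i in range(n)],
            "transcript_feature": [f"F{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
        }
    )


class TestEffectCorrelation:
    def test_monotone_transform_gives_rho_one(self, rng):
        e = rng.normal(size=20)
        res = effect_correlation(_de_table(e), _de_table(np.exp(e)), _pairs(20), "all")
        assert res.rho_obs == pytest.approx(1.0)

    def test_selection_rule_filters_layer_a(self):
        de_a = _de_table([1.0, 2.0, 3.0, 4.0, -1.0], pvals=[0.01, 0.01, 0.01, 0.5, 0.01])
        res = effect_correlation(de_a, _de_table(np.arange(5.0)), _pairs(5), "p:0.05")
        assert res.n_pairs == 4

    def test_too_few_pairs_rejected(self):
        de = _de_table([1.0, 2.0], pvals=[0.5, 0.5])
        with pytest.raises(ValueError, match="fewer than 3"):
            effect_correlation(de, de, _pairs(2), "p:0.05")

    def test_independent_layers_center_on_zero(self, rng):
        rhos = []
        for _ in range(60):
            a = _de_table(rng.normal(size=40))
            b = _de_table(rng.normal(size=40))
            rhos.append(effect_correlation(a, b, _pairs(40), "all").rho_obs)
        assert abs(np.mean(rhos)) < 2 / np.sqrt(40)


class TestPermutationEffectCorrelation:
    @pytest.fixture(scope="class")
    def small_layers(self):
        rng = np.random.default_rng(3)
        n1, n2, g = 15, 10, 40
        subjects = pd.DataFrame(
            {
                "group": ["disease"] * n1 + ["control"] * n2,
                "age": rng.normal(50, 8, n1 + n2),
                "sex": rng.choice(["F", "M"], n1 + n2),
            },
            index=pd.Index([f"S{i}" for i in range(n1 + n2)], name="subject_id"),
        )
        shared = rng.normal(0, 1.2, g) * (rng.random(g) < 0.5)
        ya = rng.normal(size=(g, n1 + n2))
        yb = rng.normal(size=(g, n1 + n2))
        ya[:, :n1] += shared[:, None]
        yb[:, :n1] += shared[:, None]
        ma = ExpressionMatrix(pd.DataFrame(ya, index=[f"F{i}" for i in range(g)], columns=subjects.index), "serum")
        mb = ExpressionMatrix(pd.DataFrame(yb, index=[f"F{i}" for i in range(g)], columns=subjects.index), "skin")
        return ma, mb, subjects

    def test_identity_permutation_reduces_to_observed(self, small_layers):
        ma, mb, subjects = small_layers
        de_a = fit_group_de(ma, subjects)
        de_b = fit_group_de(mb, subjects)
        obs = effect_correlation(de_a, de_b, _pairs(40), "all").rho_obs
        res = permutation_effect_correlation(
            ma, mb, subjects, _pairs(40), selection="all", n_perm=99, seed=0
        )
        assert res.rho_obs == pytest.approx(obs)

    def test_planted_coupling_detected(self, small_layers):
        ma, mb, subjects = small_layers
        res = permutation_effect_correlation(
            ma, mb, subjects, _pairs(40), selection="all", n_perm=199, seed=1
        )
        assert res.p_perm <= 0.02
        assert res.p_perm >= 1 / 200  # add-one floor

    def test_small_n_perm_warns(self, small_layers):
        ma, mb, subjects = small_layers
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_effect_correlation(
                ma, mb, subjects, _pairs(40), selection="all", n_perm=20, seed=0
            )


class TestDiseaseTraitConcordance:
    def test_equal_vectors_fully_concordant(self, rng):
        e = rng.normal(size=30)
        de = _de_table(e)
        trait = pd.DataFrame({"slope": e, "p": np.full(30, 0.01), "fdr": np.full(30, 0.01)},
                             index=de.index)
        res = disease_vs_trait_concordance(de, trait, cutoff=0.05)
        assert res.n_concordant == res.n_tested == 30
        assert res.rho == pytest.approx(1.0)

    def test_independent_effects_near_half_concordant(self, rng):
        fracs = []
        for _ in range(40):
            de = _de_table(rng.normal(size=50))
            trait = pd.DataFrame(
                {"slope": rng.normal(size=50), "p": np.full(50, 0.01), "fdr": np.full(50, 0.01)},
                index=de.index,
            )
            res = disease_vs_trait_concordance(de, trait, cutoff=0.05)
            fracs.append(res.n_concordant / res.n_tested)
        assert abs(np.mean(fracs) - 0.5) < 0.1

    def test_planted_shared_effects_highly_concordant(self, tiny_bundle):
        de = fit_group_de(tiny_bundle["serum"], tiny_bundle["subjects"])
        trait = trait_association(tiny_bundle["serum"], tiny_bundle["subjects"])
        res = disease_vs_trait_concordance(de, trait, cutoff=0.05)
        assert res.n_tested > 0
        assert res.n_concordant / res.n_tested >= 0.9


class TestPerGeneCrossTissue:
    def _fmap(self, genes_skin, genes_pbc):
        rows = [(f"TS{i}", g, "skin") for i, g in enumerate(genes_skin)]
        rows += [(f"TP{i}", g, "pbc") for i, g in enumerate(genes_pbc)]
        return FeatureMap(pd.DataFrame(rows, columns=["feature_id", "gene_id", "layer"]))

    def _subjects(self, n_d, n_c):
        return pd.DataFrame(
            {"group": ["disease"] * n_d + ["control"] * n_c,
             "age": 50.0, "sex": "F"},
            index=pd.Index([f"S{i}" for i in range(n_d + n_c)], name="subject_id"),
        )

    def test_identical_layers_give_rho_one(self, rng):
        genes = [f"g{i}" for i in range(6)]
        vals = rng.normal(size=(6, 12))
        skin = make_matrix(vals, layer="skin", features=[f"TS{i}" for i in range(6)],
                           samples=[f"S{i}" for i in range(12)])
        pbc = make_matrix(vals, layer="pbc", features=[f"TP{i}" for i in range(6)],
                          samples=[f"S{i}" for i in range(12)])
        out = per_gene_cross_tissue_correlation(
            skin, pbc, self._fmap(genes, genes), self._subjects(6, 6)
        )
        assert np.allclose(out["rho"], 1.0)
        assert not out["discordant"].any()

    def test_null_layers_control_fdr(self, rng):
        genes = [f"g{i}" for i in range(300)]
        skin = make_matrix(rng.normal(size=(300, 20)), layer="skin",
                           features=[f"TS{i}" for i in range(300)],
                           samples=[f"S{i}" for i in range(20)])
        pbc = make_matrix(rng.normal(size=(300, 20)), layer="pbc",
                          features=[f"TP{i}" for i in range(300)],
                          samples=[f"S{i}" for i in range(20)])
        out = per_gene_cross_tissue_correlation(
            skin, pbc, self._fmap(genes, genes), self._subjects(10, 10)
        )
        assert (out["fdr"] < 0.05).mean() <= 0.05

    def test_opposite_group_correlations_flagged_discordant(self, rng):
        genes = [f"g{i}" for i in range(5)]
        n = 16  # 8 disease + 8 control
        base = rng.normal(size=(5, n))
        skin_vals = base + 0.01 * rng.normal(size=(5, n))
        pbc_vals = np.empty_like(base)
        pbc_vals[:, :8] = base[:, :8]      # disease: positively correlated
        pbc_vals[:, 8:] = -base[:, 8:]     # control: rank-reversed
        skin = make_matrix(skin_vals, layer="skin", features=[f"TS{i}" for i in range(5)],
                           samples=[f"S{i}" for i in range(n)])
        pbc = make_matrix(pbc_vals, layer="pbc", features=[f"TP{i}" for i in range(5)],
                          samples=[f"S{i}" for i in range(n)])
        out = per_gene_cross_tissue_correlation(
            skin, pbc, self._fmap(genes, genes), self._subjects(8, 8)
        )
        assert out["discordant"].all()

    def test_no_shared_subjects_rejected(self, rng):
        skin = make_matrix(rng.normal(size=(3, 4)), layer="skin",
                           samples=[f"A{i}" for i in range(4)])
        pbc = make_matrix(rng.normal(size=(3, 4)), layer="pbc",
                          samples=[f"B{i}" for i in range(4)])
        with pytest.raises(ValueError, match="shared"):
            per_gene_cross_tissue_correlation(
                skin, pbc, self._fmap(["g"], ["g"]), self._subjects(2, 2)
            )
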