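"""Differential expression, moderation, FDR, cohort statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from triomics.containers import ExpressionMatrix
from triomics.de import (
    DesignError,
    bh_fdr,
    build_design,
    contingency_test,
    fit_group_de,
    moderate_variances,
    multivariate_group_separation,
    partial_spearman,
    rank_sum_test,
    trait_association,
    zscore_features,
)
from conftest import make_matrix


def _two_group_subjects(n1, n2, seed=0):
    rng = np.random.default_rng(seed)
    n = n1 + n2
    return pd.DataFrame(
        {
            "group": ["disease"] * n1 + ["control"] * n2,
            "age": rng.normal(50, 10, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "mrss": [float(x) for x in rng.integers(0, 40, n1)] + [np.nan] * n2,
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
    )


class TestFitGroupDE:
    def test_reduces_to_classical_two_sample_t(self, rng):
        """No covariates, moderation off: identical to the pooled-variance
        two-sample t-test, feature by feature, to 1e-12."""
        subj = _two_group_subjects(12, 9)
        y = rng.normal(0, 1, (40, 21))
        y[:5, :12] += 1.0
        m = ExpressionMatrix(pd.DataFrame(y, columns=subj.index), "serum")
        res = fit_group_de(m, subj, covariates=(), moderate=False)
        t_ref, p_ref = stats.ttest_ind(y[:, :12], y[:, 12:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, atol=1e-12)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)

    def test_planted_effect_recovery(self):
        """Planted effects of 1.5x the noise scale among mostly-null
        features are recovered with high sensitivity and controlled FDR."""
        sens, fdrs = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            subj = _two_group_subjects(49, 25, seed)
            y = rng.normal(0, 1, (1000, 74))
            y[:100, :49] += 1.5
            m = ExpressionMatrix(pd.DataFrame(y, columns=subj.index), "serum")
            res = fit_group_de(m, subj, covariates=("age", "sex"), moderate=True)
            called = res["fdr"] < 0.05
            sens.append(called[:100].mean())
            fdrs.append(called[100:].sum() / max(1, called.sum()))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdrs) <= 0.10

    def test_rank_deficient_design_names_column(self):
        subj = _two_group_subjects(6, 6)
        subj["dup"] = subj["age"]
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 12)),
                        samples=list(subj.index))
        with pytest.raises(DesignError, match="aliased"):
            fit_group_de(m, subj, covariates=("age", "dup"))

    def test_direction_matches_effect_sign(self, tiny_bundle):
        res = fit_group_de(tiny_bundle["pbc"], tiny_bundle["subjects"])
        assert (res["direction"] == np.where(res["effect"] >= 0, "up", "down")).all()


class TestModeration:
    def test_matches_published_ebayes_on_fixture(self):
        # oracle: limma::squeezeVar(c(0.5,1.2,0.8,2.0,0.3), df=10)
        params = moderate_variances(np.array([0.5, 1.2, 0.8, 2.0, 0.3]), 10)
        assert params.d0 == pytest.approx(7.108793663, abs=1e-6)
        assert params.s0_sq == pytest.approx(0.7461301216, abs=1e-6)
        np.testing.assert_allclose(
            params.posterior_var,
            [0.6022683588, 1.0114146807, 0.7776167825, 1.4790104772, 0.4853694097],
            atol=1e-6,
        )

    def test_identical_variances_shrink_completely(self):
        params = moderate_variances(np.full(10, 1.7), 8)
        assert np.isinf(params.d0)
        np.testing.assert_allclose(params.posterior_var, 1.7, rtol=1e-10)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(1)
        s2 = stats.chi2.rvs(8, size=200, random_state=rng) / 8
        params = moderate_variances(s2, 8)
        lo = np.minimum(s2, params.s0_sq)
        hi = np.maximum(s2, params.s0_sq)
        assert ((params.posterior_var >= lo - 1e-12) & (params.posterior_var <= hi + 1e-12)).all()

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            moderate_variances(np.array([1.0, 2.0]), 5)


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_agrees_with_brute_force_stepup(self, rng):
        """Matches the literal step-up definition q_(i) = min_j>=i n p_(j)/j
        on many random vectors."""
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            q = bh_fdr(p)
            order = np.argsort(p, kind="stable")
            n = len(p)
            brute = np.empty(n)
            for i_rank, idx in enumerate(order):
                cand = [n * p[order[j]] / (j + 1) for j in range(i_rank, n)]
                brute[idx] = min(1.0, min(cand))
            np.testing.assert_allclose(q, brute, atol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))


class TestContingency:
    @pytest.mark.parametrize(
        "table,expected,digits",
        [
            ((1, 31, 6, 11), 0.008, 3),   # anti-centromere, diffuse vs limited
            ((10, 22, 4, 13), 0.81, 2),   # immunosuppressive agent
            ((17, 13, 2, 15), 0.007, 3),  # interstitial lung disease
            ((2, 30, 1, 16), 1.0, 1),     # ribonucleoprotein antibodies
        ],
    )
    def test_reported_cohort_tables(self, table, expected, digits):
        _, p = contingency_test(*table)
        assert round(p, digits) == expected

    def test_symmetric_table_gives_p_one(self):
        chi2, p = contingency_test(5, 5, 5, 5)
        assert chi2 == 0.0
        assert p == 1.0

    def test_matches_scipy_on_small_tables(self):
        """Exhaustive check against scipy's continuity-corrected chi2 on
        all 2x2 tables with entries in 1..6."""
        from itertools import product

        for a, b, c, d in product(range(1, 7), repeat=4):
            chi2, p = contingency_test(a, b, c, d)
            chi2_ref, p_ref, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert chi2 == pytest.approx(chi2_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test(0, 0, 3, 4)


class TestRankSum:
    def test_exact_small_sample(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0, abs=0.05)

    def test_asymptotic_close_to_exact(self, rng):
        diffs = []
        for _ in range(30):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            diffs.append(abs(exact - approx))
        assert max(diffs) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestPartialSpearman:
    def test_reduces_to_spearman_with_constant_covariate(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho = stats.spearmanr(x, y).statistic
        rho_part = partial_spearman(x, y, [np.ones(30)])
        assert rho_part == pytest.approx(rho, abs=1e-10)

    def test_fully_explained_y_gives_zero(self, rng):
        cov = rng.normal(size=40)
        x = rng.normal(size=40)
        assert abs(partial_spearman(x, cov, [cov])) < 1e-8

    def test_x_equals_y_gives_one(self, rng):
        x = rng.normal(size=25)
        cov = rng.normal(size=25)
        assert partial_spearman(x, x, [cov]) == pytest.approx(1.0, abs=1e-10)

    def test_irrelevant_covariates_change_little(self, rng):
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        rho = stats.spearmanr(x, y).statistic
        rho_part = partial_spearman(x, y, [rng.normal(size=500)])
        assert abs(rho_part - rho) < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(10), np.arange(10), [np.arange(10)])


class TestTraitAssociation:
    def test_monotone_trait_gives_rho_one(self, rng):
        subj = _two_group_subjects(15, 0, seed=2)
        expr = np.vstack([subj["mrss"].to_numpy() ** 2, rng.normal(size=15)])
        m = make_matrix(expr, samples=list(subj.index))
        res = trait_association(m, subj)
        assert res.loc["F0", "rho"] == pytest.approx(1.0, abs=1e-10)

    def test_planted_trait_features_rank_first(self, tiny_bundle):
        truth = tiny_bundle["truth"]
        res = trait_association(tiny_bundle["serum"], tiny_bundle["subjects"])
        planted = [f for f in truth.de_features["serum"] if f in res.index]
        null_p = res.drop(index=planted)["p"]
        assert res.loc[planted, "p"].median() < null_p.median()

    def test_constant_trait_rejected(self):
        subj = _two_group_subjects(6, 0)
        subj["mrss"] = 10.0
        m = make_matrix(np.random.default_rng(0).normal(size=(3, 6)),
                        samples=list(subj.index))
        with pytest.raises(DesignError, match="constant"):
            trait_association(m, subj)


class TestZscore:
    def test_hand_example(self):
        out = zscore_features(make_matrix([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_idempotent_and_centered(self, tiny_bundle):
        z1 = zscore_features(tiny_bundle["serum"])
        z2 = zscore_features(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)
        assert np.abs(z1.to_numpy().mean(axis=1)).max() < 1e-12

    def test_zero_variance_feature_named(self):
        m = make_matrix([[1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="F0"):
            zscore_features(m)


class TestMultivariateSeparation:
    def test_separated_groups_detected(self, rng):
        y = rng.normal(0, 1, (50, 60))
        y[:, :40] += 2.0  # strong shift on many features for one group
        m = make_matrix(y, samples=[f"S{i}" for i in range(60)])
        groups = pd.Series(["disease"] * 40 + ["control"] * 20, index=m.sample_ids)
        res = multivariate_group_separation(m, groups, k_components=2, n_perm=199, seed=1)
        assert res["p"] <= 0.01

    def test_too_many_components_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 6)))
        groups = pd.Series(["disease"] * 3 + ["control"] * 3, index=m.sample_ids)
        with pytest.raises(ValueError):
            multivariate_group_separation(m, groups, k_components=6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=50))
def test_bh_fdr_monotone_in_p_rank(pvals):
    """BH q-values never decrease with increasing p, and stay within [0,1]."""
    p = np.array(pvals)
    q = bh_fdr(p)
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()
    assert ((q >= 0) & (q <= 1)).all()
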