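"""Hotelling T², residual permutation, Pearson, and the fullness mixed model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophicniche import inference, simulate
from trophicniche.datatypes import InsufficientDataError, ValidationError

from ._oracles import hotelling_oracle, pearson_oracle

TIMES = [1, 4, 7, 10, 13, 16, 19, 22]


class TestHotelling:
    def test_identical_samples_give_zero_statistic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 2))
        res = inference.hotelling_t2(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = rng.normal(size=(rng.integers(5, 20), 2))
            b = rng.normal(loc=0.5, size=(rng.integers(5, 20), 2))
            res = inference.hotelling_t2(a, b)
            assert res.statistic == pytest.approx(hotelling_oracle(a, b), abs=1e-9)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 2))
        b = rng.normal(loc=0.8, size=(15, 2))
        ours = inference.hotelling_t2(a, b)
        theirs = pg.multivariate_ttest(a, b)
        assert ours.statistic == pytest.approx(float(theirs["T2"].iloc[0]), rel=1e-9)
        assert ours.p_value == pytest.approx(float(theirs["pval"].iloc[0]), rel=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_common_affine_maps(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 2))
        b = rng.normal(loc=1.0, size=(9, 2))
        m = rng.normal(size=(2, 2))
        if abs(np.linalg.det(m)) < 0.1:
            return
        shift = rng.normal(size=2)
        base = inference.hotelling_t2(a, b).statistic
        mapped = inference.hotelling_t2(a @ m.T + shift, b @ m.T + shift).statistic
        assert mapped == pytest.approx(base, rel=1e-8)

    def test_singular_pooled_covariance_rejected(self):
        # both groups collinear on the same axis -> rank-1 pooled covariance
        a = np.column_stack([np.arange(5.0), np.zeros(5)])
        b = np.column_stack([np.arange(5.0) + 1, np.zeros(5)])
        with pytest.raises(ValidationError):
            inference.hotelling_t2(a, b)


class TestRpp:
    def test_no_signal_gives_large_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 2))
        res = inference.rpp_test(a, a.copy(), metric="CD", B=199, seed=0)
        assert res.p_value > 0.5

    def test_translation_detected_at_resolution_limit(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(12, 2))
        res = inference.rpp_test(a, a + 10.0, metric="centroid_distance",
                                 B=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    @pytest.mark.parametrize("metric", ["CD", "MNND", "centroid_distance"])
    def test_p_value_respects_add_one_bound(self, metric):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(10, 2))
        b = rng.normal(loc=3.0, size=(10, 2))
        res = inference.rpp_test(a, b, metric=metric, B=99, seed=2)
        assert res.p_value >= 1 / 100
        assert res.permutations == 99

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValidationError):
            inference.rpp_test(np.zeros((5, 2)), np.ones((5, 2)), B=10)


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = inference.pearson(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)

    def test_orthogonal_contrast_is_uncorrelated(self):
        res = inference.pearson([1.0, 2.0, 3.0], [1.0, 0.0, 1.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        y = 0.3 * x + rng.normal(size=25)
        res = inference.pearson(x, y)
        assert res.statistic == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            inference.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFullnessLmm:
    def test_zero_season_variance_degenerates_to_ols(self):
        import statsmodels.formula.api as smf

        cfg = simulate.FullnessSimConfig(season_sd=0.0, seed=20)
        ft = simulate.simulate_fullness(cfg)
        fit = inference.fit_lmm(ft, "additive")
        assert fit.season_variance < 0.01
        ols = smf.ols("ff ~ C(group) + C(time_h)", ft.data).fit()
        for name, est in fit.fixed_effects.items():
            assert est == pytest.approx(ols.params[name], abs=1e-4)

    def test_recovers_simulated_effects_within_2se(self):
        effects = {t: e for t, e in zip(TIMES, (0, 0.5, 1.0, 0.2, -0.3, 0.8, 0.4, 0))}
        cfg = simulate.FullnessSimConfig(
            time_effects=effects, season_sd=0.5,
            seasons=[f"s{i}" for i in range(6)], n_per_cell=4, seed=21,
        )
        ft = simulate.simulate_fullness(cfg)
        fit = inference.fit_lmm(ft, "additive")
        missed = 0
        for t in TIMES[1:]:
            name = f"C(time_h)[T.{t}]"
            truth = effects[t] - effects[TIMES[0]]
            if abs(fit.fixed_effects[name] - truth) > 2 * fit.fixed_effects_se[name]:
                missed += 1
        assert missed <= 2  # ~95% coverage over 7 contrasts

    def test_refit_is_deterministic(self):
        ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=22))
        f1 = inference.fit_lmm(ft, "full")
        f2 = inference.fit_lmm(ft, "full")
        assert f1.log_likelihood == f2.log_likelihood

    def test_single_season_rejected(self):
        cfg = simulate.FullnessSimConfig(seasons=["only"], seed=23)
        ft = simulate.simulate_fullness(cfg)
        with pytest.raises(InsufficientDataError):
            inference.fit_lmm(ft, "additive")


class TestLrt:
    def test_identical_models_compare_trivially(self):
        ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=24))
        fit = inference.fit_lmm(ft, "additive")
        res = inference.lrt_compare(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_chi2_nonnegative_and_additive_over_nested_chain(self):
        ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=25))
        full = inference.fit_lmm(ft, "additive")
        mid = inference.fit_lmm(ft, "time")
        null = inference.fit_lmm(ft, "null")
        a = inference.lrt_compare(full, mid).statistic
        b = inference.lrt_compare(mid, null).statistic
        c = inference.lrt_compare(full, null).statistic
        assert a >= 0 and b >= 0
        assert c == pytest.approx(a + b, abs=1e-6)

    def test_non_nested_order_rejected(self):
        ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=26))
        full = inference.fit_lmm(ft, "additive")
        red = inference.fit_lmm(ft, "time")
        with pytest.raises(ValidationError):
            inference.lrt_compare(red, full)

    def test_rhythm_tests_report_all_terms(self):
        ft = simulate.simulate_fullness(simulate.FullnessSimConfig(seed=27))
        out = inference.rhythm_tests(ft)
        assert set(out) == {"interaction", "time", "group"}
        assert all(0 <= t.p_value <= 1 for t in out.values())
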