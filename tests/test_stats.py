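"""Statistical procedures: hand-computed oracles and calibration properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pseudodxa.stats import (
    StatsError,
    age_adjust,
    ancova_compare,
    dagostino_pearson,
    icc,
    independent_t_test,
    linreg,
    multivariable_fit,
    pct_difference,
)


class TestTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = independent_t_test(a, a)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # means 2 and 5, pooled SD 1, SE = sqrt(2/3): t = -3/0.8165 = -3.674
        t, p = independent_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=2e-3)

    def test_unequal_n_accepted(self):
        t, p = independent_t_test([1, 2, 3, 4], [2, 3])
        assert np.isfinite(t) and 0 <= p <= 1

    def test_too_small_group(self):
        with pytest.raises(StatsError):
            independent_t_test([1.0], [2.0, 3.0])


class TestNormality:
    def test_normal_draws_usually_pass(self):
        rejections = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=5000)
            _, p = dagostino_pearson(x)
            rejections += p <= 0.05
        assert rejections <= 2  # >= 90% of seeds non-significant

    def test_exponential_draws_fail(self):
        x = np.random.default_rng(0).exponential(size=5000)
        _, p = dagostino_pearson(x)
        assert p < 0.001

    def test_small_sample_error(self):
        with pytest.raises(StatsError, match="n >= 20"):
            dagostino_pearson([1.0] * 5)


class TestAgeAdjust:
    def test_all_at_target_age_unchanged(self):
        df = pd.DataFrame({"sex": [0, 0, 0, 1, 1, 1], "age": 65.0,
                           "v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        out, slopes = age_adjust(df, ["v"])
        assert np.allclose(out["v"], df["v"])

    def test_exact_line_collapses_to_target(self):
        df = pd.DataFrame({"sex": 0, "age": [60.0, 70.0, 50.0], "v": [120.0, 140.0, 100.0]})
        out, slopes = age_adjust(df, ["v"])
        assert np.allclose(out["v"], 130.0)
        assert slopes[(0, "v")] == pytest.approx(2.0)

    def test_known_slope_removed(self, rng):
        """After adjustment, the variable no longer regresses on age."""
        n = 400
        age = rng.uniform(30, 90, n)
        v = 10.0 - 0.25 * age + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"sex": np.zeros(n, dtype=int), "age": age, "v": v})
        out, _ = age_adjust(df, ["v"])
        res = linreg(out["age"], out["v"])
        se = (res.slope_ci[1] - res.slope_ci[0]) / 4.0
        assert abs(res.slope) < 2 * se + 1e-9

    def test_small_group_error(self):
        df = pd.DataFrame({"sex": [0, 0, 1], "age": [60, 70, 65], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(StatsError):
            age_adjust(df, ["v"])


class TestLinreg:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = linreg(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0) and res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_closed_form_ols(self):
        res = linreg([0.0, 1.0, 2.0], [0.0, 1.0, 3.0])
        assert res.slope == pytest.approx(1.5)
        assert res.intercept == pytest.approx(-1.0 / 6.0)

    def test_degenerate_inputs(self):
        with pytest.raises(StatsError):
            linreg([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(StatsError):
            linreg([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAncova:
    def test_identical_groups_zero_difference(self):
        x = np.tile(np.linspace(0, 10, 30), 2)
        y = 3 * x + np.tile(np.random.default_rng(0).normal(0, 1, 30), 2)
        g = np.repeat([0, 1], 30)
        res = ancova_compare(x, y, g)
        assert res.elevation_diff == pytest.approx(0.0, abs=1e-9)
        assert res.pct_difference == pytest.approx(0.0, abs=1e-9)

    def test_injected_offset_recovered(self, rng):
        n = 200
        x = rng.normal(30, 5, 2 * n)
        g = np.repeat([0, 1], n)
        y = 3 * x + 1045.0 * g + rng.normal(0, 50, 2 * n)
        res = ancova_compare(x, y, g)
        se = (res.elevation_diff_ci[1] - res.elevation_diff_ci[0]) / 4.0
        assert abs(res.elevation_diff - 1045.0) < 2 * se
        assert res.elevation_p < 1e-6

    def test_slope_difference_detected(self, rng):
        n = 200
        x = rng.normal(10, 3, 2 * n)
        g = np.repeat([0, 1], n)
        y = (1.0 + g) * x + rng.normal(0, 1.0, 2 * n)
        assert ancova_compare(x, y, g).slope_p < 0.01

    def test_midpoint_shift_does_not_change_slope_or_r2(self, rng):
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 0.5, 50)
        base = linreg(x, y)
        shifted = linreg(x - 17.3, y)
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.r2 == pytest.approx(base.r2)

    def test_zero_x_variance_group(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        y = np.arange(6.0)
        g = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(StatsError):
            ancova_compare(x, y, g)


class TestPctDifference:
    @pytest.mark.parametrize(
        "female, male, diff, pct",
        [
            (3773.0, 4272.0, 499.0, 12.4),
            (3586.0, 4629.0, 1043.0, 25.4),
            (3561.0, 4606.0, 1045.0, 25.6),
            (3429.0, 4790.0, 1361.0, 33.1),
            (3262.0, 5042.0, 1780.0, 42.9),
        ],
    )
    def test_elevation_pairs(self, female, male, diff, pct):
        assert male - female == pytest.approx(diff)
        assert pct_difference(female, male) == pytest.approx(pct, abs=0.05)

    def test_equal_inputs(self):
        assert pct_difference(5.0, 5.0) == 0.0

    def test_non_positive_rejected(self):
        with pytest.raises(StatsError):
            pct_difference(-1.0, 2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(1e-3, 1e6, allow_nan=False),
        st.floats(1e-3, 1e6, allow_nan=False),
    )
    def test_antisymmetry_and_bounds(self, a, b):
        assert pct_difference(a, b) == pytest.approx(-pct_difference(b, a))
        assert -200.0 < pct_difference(a, b) < 200.0


class TestMultivariable:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        y = 1.0 + 2 * X["a"] - X["b"] + np.random.default_rng(0).normal(0, 0.1, n)
        fit = multivariable_fit(y.to_numpy(), X)
        for term in fit.terms:
            assert term.vif == pytest.approx(1.0, abs=1e-6)
        assert fit.removed == []

    def test_duplicated_predictor_removed(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = pd.DataFrame({"x1": x, "x2": x + rng.normal(0, 1e-8, n), "z": rng.normal(size=n)})
        y = x + rng.normal(0, 0.1, n)
        fit = multivariable_fit(y, X)
        assert len(fit.removed) == 1 and fit.removed[0] in ("x1", "x2")
        assert all(t.vif <= 10 for t in fit.terms)

    def test_standardized_beta_sign_matches_b(self, rng):
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = 3 * X["a"] - 2 * X["b"] + rng.normal(0, 1, n)
        fit = multivariable_fit(y.to_numpy(), X)
        for t in fit.terms:
            assert np.sign(t.beta_std) == np.sign(t.b)


class TestIcc:
    def test_identical_columns(self):
        x = np.linspace(0, 1, 12)
        val, _ = icc(np.column_stack([x, x]))
        assert val == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        r = rng.normal(size=(100, 2))
        val, _ = icc(r)
        assert abs(val) < 0.2  # within ~2 SE of zero at n = 100

    def test_missing_cells_rejected(self):
        r = np.ones((6, 2))
        r[0, 0] = np.nan
        with pytest.raises(StatsError):
            icc(r)

    def test_too_few_subjects(self):
        with pytest.raises(StatsError):
            icc(np.ones((3, 2)))
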