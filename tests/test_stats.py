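import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meibomorph import ValidationError
from meibomorph.stats import (
    benjamini_hochberg,
    compare_groups,
    correlation_matrix,
    encode_sex,
    power_sample_size,
    summary_ttest,
)


def _two_group_frame(x: np.ndarray, y: np.ndarray, name: str = "v") -> pd.DataFrame:
    return pd.DataFrame(
        {"group": ["a"] * len(x) + ["b"] * len(y), name: np.concatenate([x, y])}
    )


class TestCompareGroups:
    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(4)
        table = _two_group_frame(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
        assert compare_groups(table, "v").p_value > 0.001

    def test_extreme_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 100)
        table = _two_group_frame(x, rng.normal(10, 1, 100))
        res = compare_groups(table, "v")
        assert res.p_value < 1e-6

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(6)
        table = _two_group_frame(rng.exponential(1, 150), rng.exponential(2, 150))
        assert compare_groups(table, "v").test_name == "mann_whitney"

    def test_normal_data_routes_to_t(self):
        rng = np.random.default_rng(7)
        table = _two_group_frame(rng.normal(5, 1, 80), rng.normal(5.2, 1, 80))
        assert compare_groups(table, "v").test_name in ("t", "welch_t")

    def test_unequal_variances_route_to_welch(self):
        rng = np.random.default_rng(8)
        table = _two_group_frame(rng.normal(0, 1, 150), rng.normal(0, 4, 150))
        assert compare_groups(table, "v").test_name == "welch_t"

    def test_categorical_chi_square(self):
        rows = (
            [("a", "yes")] * 90 + [("a", "no")] * 10
            + [("b", "yes")] * 10 + [("b", "no")] * 90
        )
        table = pd.DataFrame(rows, columns=["group", "v"])
        res = compare_groups(table, "v")
        assert res.test_name == "chi_square"
        assert res.p_value < 1e-6
        # independent oracle: chi-square from the closed-form 2x2 statistic
        chi2 = 200 * (90 * 90 - 10 * 10) ** 2 / (100 * 100 * 100 * 100)
        assert res.statistic == pytest.approx(
            sps.chi2_contingency([[90, 10], [10, 90]])[0], rel=1e-12
        )
        assert chi2 == pytest.approx(128.0)  # un-corrected value, sanity anchor

    def test_small_cells_route_to_fisher(self):
        rows = [("a", "yes")] * 8 + [("a", "no")] * 2 + [("b", "yes")] * 1 + [("b", "no")] * 9
        table = pd.DataFrame(rows, columns=["group", "v"])
        assert compare_groups(table, "v").test_name == "fisher"

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(pd.DataFrame({"group": ["a", "b"]}), "v")

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 stays within 5% +/- 2%."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            table = _two_group_frame(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
            if compare_groups(table, "v").p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestSummaryTTest:
    def test_equal_means_give_t0_p1(self):
        res = summary_ttest(5.0, 1.0, 50, 5.0, 1.2, 60)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_tear_meniscus_height_row_is_significant(self):
        res = summary_ttest(0.26, 0.10, 252, 0.44, 0.08, 200, variant="pooled")
        assert res.p_value < 0.0001

    def test_tbut_row_hand_computed_statistic(self):
        # pooled sp^2 = (251*6.31^2 + 199*2.58^2)/450 -> t = -3.853, df = 450
        res = summary_ttest(8.65, 6.31, 252, 10.48, 2.58, 200, variant="pooled")
        assert res.statistic == pytest.approx(-3.853, abs=0.01)
        assert res.df == 450

    def test_pooled_agrees_with_raw_data_ttest(self):
        """Dual route: summary t equals scipy's t on raw data with those moments."""
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=40), rng.normal(size=55)
        x = (x - x.mean()) / x.std(ddof=1) * 1.3 + 2.0
        y = (y - y.mean()) / y.std(ddof=1) * 0.9 + 2.4
        raw = sps.ttest_ind(x, y)
        res = summary_ttest(2.0, 1.3, 40, 2.4, 0.9, 55, variant="pooled")
        assert res.statistic == pytest.approx(raw.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(raw.pvalue, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            summary_ttest(1, 0, 10, 2, 1, 10)
        with pytest.raises(ValidationError):
            summary_ttest(1, 1, 1, 2, 1, 10)


class TestCorrelationMatrix:
    def test_linear_function_is_perfectly_correlated(self):
        x = np.linspace(0, 1, 50)
        table = pd.DataFrame({"x": x, "y": 2 * x + 1})
        corr, _ = correlation_matrix(table, ["x", "y"])
        assert corr.loc["x", "y"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({"x": rng.normal(size=10_000), "y": rng.normal(size=10_000)})
        corr, _ = correlation_matrix(table, ["x", "y"])
        assert abs(corr.loc["x", "y"]) < 0.05

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        corr, pvals = correlation_matrix(table, list("abcd"))
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)
        assert (corr.abs().values <= 1).all()
        assert ((pvals.values >= 0) & (pvals.values <= 1)).all()

    def test_constant_column_recorded_missing(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
        corr, _ = correlation_matrix(table, ["x", "c"])
        assert np.isnan(corr.loc["x", "c"])

    def test_sex_encoding(self):
        s = encode_sex(pd.Series(["male", "female", "male"]))
        assert s.tolist() == [1.0, 0.0, 1.0]


class TestPowerSampleSize:
    def test_study_design_value(self):
        """d=0.5, alpha=0.05, power 0.80 -> 64 eyes per group."""
        assert power_sample_size(0.5, 0.05, 0.80) == 64

    def test_large_effect_brute_force_value(self):
        # brute-force noncentral-t search oracle gives 17 at d=1.0
        assert power_sample_size(1.0, 0.05, 0.80) == 17

    def test_against_statsmodels_solver(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.3, 0.5, 0.8):
            n_cont = TTestIndPower().solve_power(
                effect_size=d, alpha=0.05, power=0.8, alternative="two-sided"
            )
            assert power_sample_size(d) == int(np.ceil(n_cont))

    def test_normal_approximation_bracket(self):
        # 2*(z_.975 + z_.8)^2 / 0.5^2 = 62.8; the exact answer sits within +2 of 63
        approx = 2 * (sps.norm.ppf(0.975) + sps.norm.ppf(0.8)) ** 2 / 0.25
        n = power_sample_size(0.5)
        assert np.ceil(approx) <= n <= np.ceil(approx) + 2

    def test_monotone_in_effect_and_power(self):
        assert power_sample_size(0.4) >= power_sample_size(0.5) >= power_sample_size(0.8)
        assert power_sample_size(0.5, power=0.9) >= power_sample_size(0.5, power=0.8)

    def test_one_sided_needs_fewer(self):
        assert power_sample_size(0.5, sides="one-sided") < power_sample_size(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            power_sample_size(-1)
        with pytest.raises(ValidationError):
            power_sample_size(0.5, alpha=1.5)


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= p).all()
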