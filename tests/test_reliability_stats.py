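"""Reliability battery vs independent definitional and pingouin oracles."""

import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from sicisim.reliability_stats import (
    MeasurementMatrix,
    bland_altman,
    bonferroni_posthoc,
    classify_icc,
    coefficient_of_repeatability,
    icc_2_1,
    method_regression,
    one_sample_condition_test,
    paired_t,
    rm_anova,
    within_subject_sd,
)


def _random_matrix(rng, n=None, k=None):
    n = n or rng.integers(5, 15)
    k = k or rng.integers(2, 5)
    x = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 1.5
    return MeasurementMatrix(x)


def _long(x):
    n, k = x.shape
    return pd.DataFrame(
        {
            "subj": np.repeat(np.arange(n), k),
            "rep": np.tile(np.arange(k), n),
            "y": x.ravel(),
        }
    )


class TestWithinSubjectSd:
    def test_identical_repeats_zero(self):
        m = MeasurementMatrix(np.tile([[1.0], [2.0], [3.0]], (1, 3)))
        assert within_subject_sd(m) == 0.0

    def test_two_repeat_closed_form(self):
        # paired diffs {1,-1,1,-1}: sigma_w = sqrt(4/8)
        x = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 1.0], [1.0, 2.0]])
        assert within_subject_sd(MeasurementMatrix(x)) == pytest.approx(
            math.sqrt(0.5)
        )

    def test_matches_one_way_anova_oracle(self):
        """sigma_w equals sqrt(MS within) from a definitional one-way ANOVA."""
        rng = np.random.default_rng(21)
        for _ in range(100):
            m = _random_matrix(rng)
            x = m.values
            ss = 0.0
            for row in x:  # independent loop-coded oracle
                mean = sum(row) / len(row)
                ss += sum((v - mean) ** 2 for v in row)
            oracle = math.sqrt(ss / (x.shape[0] * (x.shape[1] - 1)))
            assert within_subject_sd(m) == pytest.approx(oracle, abs=1e-10)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            within_subject_sd(MeasurementMatrix(np.ones((3, 1))))


class TestCoefficientOfRepeatability:
    def test_identical_repeats_zero(self):
        m = MeasurementMatrix(np.tile([[1.0], [2.0]], (1, 2)))
        assert coefficient_of_repeatability(m)[0] == 0.0

    def test_closed_form(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 1.0], [1.0, 2.0]])
        cr, _ = coefficient_of_repeatability(MeasurementMatrix(x))
        assert cr == pytest.approx(1.96, abs=1e-12)

    def test_tenfold_log_duplicates_backtransform(self):
        """Duplicates differing 10-fold give a 91.2-fold back-transformed CR."""
        base = np.array([0.0, 1.0, -1.0, 0.5])
        x = np.column_stack([base, base + 1.0])  # 1 log10 unit apart
        m = MeasurementMatrix(x, scale="log10")
        sw = within_subject_sd(m)
        assert sw == pytest.approx(math.sqrt(0.5), abs=1e-12)
        cr, _ = coefficient_of_repeatability(m)
        assert 10**cr == pytest.approx(91.2, rel=0.001)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        m = _random_matrix(rng, n=10, k=2)
        cr, (lo, hi) = coefficient_of_repeatability(m)
        assert lo < cr < hi

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(c=st.floats(0.1, 50), seed=st.integers(0, 2**16))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        cr1, _ = coefficient_of_repeatability(MeasurementMatrix(x))
        cr2, _ = coefficient_of_repeatability(MeasurementMatrix(c * x))
        assert cr2 == pytest.approx(abs(c) * cr1, rel=1e-9)


class TestIcc:
    def test_identical_columns_distinct_rows(self):
        x = np.tile([[1.0], [2.0], [5.0]], (1, 3))
        icc, _ = icc_2_1(MeasurementMatrix(x))
        assert icc == pytest.approx(1.0)

    def test_hand_computed_mean_squares(self):
        icc, _ = icc_2_1(MeasurementMatrix([[1, 2], [3, 4], [5, 6]]))
        assert icc == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            m = _random_matrix(rng, n=10, k=2)
            icc, (lo, hi) = icc_2_1(m)
            tab = pg.intraclass_corr(
                _long(m.values), targets="subj", raters="rep", ratings="y"
            )
            row = tab[tab["Type"] == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-10)
            assert lo == pytest.approx(row["CI95"][0], abs=0.01)
            assert hi == pytest.approx(row["CI95"][1], abs=0.01)

    def test_matches_definitional_variance_components_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(100):
            m = _random_matrix(rng, n=10, k=2)
            x = m.values
            n, k = x.shape
            grand = x.mean()
            msr = k * sum((r.mean() - grand) ** 2 for r in x) / (n - 1)
            msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
            sse = sum(
                (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
                for i in range(n)
                for j in range(k)
            )
            mse = sse / ((n - 1) * (k - 1))
            oracle = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
            assert icc_2_1(m)[0] == pytest.approx(oracle, abs=1e-10)

    def test_two_repeat_paired_sum_difference_oracle(self):
        """For k=2 the same ICC comes from the paired sum/difference
        decomposition of the mean squares."""
        rng = np.random.default_rng(35)
        x = rng.normal(size=(12, 2)) + rng.normal(size=(12, 1))
        a, b = x[:, 0], x[:, 1]
        n = len(a)
        grand = (a.sum() + b.sum()) / (2 * n)
        s = (a + b) / 2.0
        d = a - b
        msr = 2.0 * ((s - grand) ** 2).sum() / (n - 1)
        msc = n * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        # for k=2 the interaction SS is half the centred squared differences
        mse = (((d - d.mean()) ** 2).sum() / 2.0) / (n - 1)
        oracle = (msr - mse) / (msr + mse + 2.0 / n * (msc - mse))
        assert icc_2_1(MeasurementMatrix(x))[0] == pytest.approx(oracle, abs=1e-10)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(36)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        icc1, _ = icc_2_1(MeasurementMatrix(x))
        icc2, _ = icc_2_1(MeasurementMatrix(x + 7.5))
        assert icc1 == pytest.approx(icc2, abs=1e-10)

    def test_noise_degrades_icc_in_expectation(self):
        rng = np.random.default_rng(37)
        lows, highs = [], []
        for _ in range(30):
            signal = rng.normal(size=(10, 1)) * np.ones((1, 3))
            lows.append(icc_2_1(MeasurementMatrix(signal + rng.normal(size=(10, 3)) * 0.3))[0])
            highs.append(icc_2_1(MeasurementMatrix(signal + rng.normal(size=(10, 3)) * 1.5))[0])
        assert np.median(lows) > np.median(highs)

    def test_zero_variance_undefined(self):
        icc, ci = icc_2_1(MeasurementMatrix(np.ones((4, 3))))
        assert math.isnan(icc) and math.isnan(ci[0])


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (0.45, "poor"),
            (0.50, "moderate"),
            (0.749, "moderate"),
            (0.75, "good"),
            (0.82, "good"),
            (0.90, "good"),
            (0.91, "excellent"),
            (float("nan"), "undefined"),
        ],
    )
    def test_bands(self, icc, band):
        assert classify_icc(icc) == band


class TestRmAnova:
    def test_two_levels_trivially_spherical(self):
        rng = np.random.default_rng(41)
        res = rm_anova(MeasurementMatrix(rng.normal(size=(8, 2))))
        assert res.epsilon == 1.0 and res.mauchly_p == 1.0

    def test_equal_column_means_f_zero(self):
        rng = np.random.default_rng(42)
        col = rng.normal(size=(8, 1))
        noise = rng.normal(size=(8, 3))
        noise -= noise.mean(axis=0, keepdims=True)  # force equal column means
        res = rm_anova(MeasurementMatrix(np.tile(col, (1, 3)) + noise))
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            m = _random_matrix(rng, n=12, k=4)
            mine = rm_anova(m)
            long = _long(m.values)
            aov = pg.rm_anova(
                data=long, dv="y", within="rep", subject="subj", correction=True
            )
            assert mine.F == pytest.approx(float(aov["F"].iloc[0]), abs=1e-8)
            eps = float(pg.epsilon(long, dv="y", within="rep", subject="subj",
                                   correction="gg"))
            assert mine.epsilon == pytest.approx(eps, abs=1e-8)
            sph = pg.sphericity(long, dv="y", within="rep", subject="subj")
            # first-order vs second-order chi2 approximations
            assert mine.mauchly_p == pytest.approx(sph.pval, abs=5e-3)
            if abs(sph.pval - 0.05) > 0.02:
                expect = (
                    float(aov["p_unc"].iloc[0])
                    if sph.pval >= 0.05
                    else float(aov["p_GG_corr"].iloc[0])
                )
                assert mine.p == pytest.approx(expect, abs=1e-8)

    def test_posthoc_bonferroni_scaling(self):
        rng = np.random.default_rng(44)
        m = _random_matrix(rng, n=10, k=3)
        tab = bonferroni_posthoc(m)
        assert len(tab) == 3
        assert np.all(
            tab["p_bonferroni"] == np.minimum(1.0, tab["p_uncorrected"] * 3)
        )


class TestBlandAltman:
    def test_identical_pairs(self):
        a = np.array([1.0, 2.0, 3.0])
        assert bland_altman(a, a) == (0.0, 0.0, 0.0)

    def test_symmetric_diffs_closed_form(self):
        bias, lo, hi = bland_altman(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert bias == 0.0
        assert hi == pytest.approx(1.96 * math.sqrt(2.0), abs=1e-9)
        assert lo == pytest.approx(-1.96 * math.sqrt(2.0), abs=1e-9)

    def test_log_scale_constant_ratio(self):
        a = np.log10([2.0, 4.0, 8.0])
        b = np.log10([1.0, 2.0, 4.0])
        bias, lo, hi = bland_altman(a, b, scale="log10")
        assert (bias, lo, hi) == pytest.approx((2.0, 2.0, 2.0))

    def test_antisymmetry(self):
        rng = np.random.default_rng(51)
        a, b = rng.normal(size=10), rng.normal(size=10)
        bias_ab, lo_ab, hi_ab = bland_altman(a, b)
        bias_ba, lo_ba, hi_ba = bland_altman(b, a)
        assert bias_ab == pytest.approx(-bias_ba)
        assert lo_ab == pytest.approx(-hi_ba) and hi_ab == pytest.approx(-lo_ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones(3), np.ones(4))


class TestTTests:
    def test_all_equal_null(self):
        t, df, p = one_sample_condition_test(np.array([5.0, 5.0, 5.0]), 5.0)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form(self):
        t, df, p = one_sample_condition_test(np.array([1.0, 2.0, 3.0]), 0.0)
        assert t == pytest.approx(2.0 * math.sqrt(3.0), abs=1e-9)
        assert df == 2

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            one_sample_condition_test(np.array([1.0]), 0.0)

    def test_paired_t_matches_one_sample_of_diffs(self):
        rng = np.random.default_rng(61)
        a, b = rng.normal(size=8), rng.normal(size=8)
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = one_sample_condition_test(a - b, 0.0)
        assert t1 == pytest.approx(t2) and p1 == pytest.approx(p2)


class TestMethodRegression:
    def test_collinear(self):
        a = np.array([10.0, 100.0, 1000.0])  # log10 = 1, 2, 3
        t = np.array([0.0, 1.0, 2.0])
        res = method_regression(t, a)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(-1.0)

    def test_monte_carlo_correlation(self):
        rng = np.random.default_rng(62)
        n = 5000
        x = rng.normal(size=n)
        y = 0.8 * x + math.sqrt(1 - 0.64) * rng.normal(size=n)
        res = method_regression(y, 10.0**x)
        assert res.r == pytest.approx(0.8, abs=0.02)
        assert res.r_ci95[0] < 0.8 < res.r_ci95[1]

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            method_regression(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))

    def test_nonpositive_a_sici_rejected(self):
        with pytest.raises(ValueError):
            method_regression(np.array([1.0, 2.0, 3.0]), np.array([1.0, -2.0, 3.0]))


class TestMeasurementMatrix:
    def test_listwise_deletion(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, 5.0]])
        m = MeasurementMatrix(x)
        assert m.n_subjects == 2 and m.n_dropped == 1

    def test_round_trip_wide_csv(self, tmp_path):
        x = np.arange(8.0).reshape(4, 2)
        df = pd.DataFrame(x, columns=["exam1", "exam2"])
        path = tmp_path / "wide.csv"
        df.to_csv(path)
        m = MeasurementMatrix.from_wide_csv(path, parameter_name="RMT")
        np.testing.assert_allclose(m.values, x)
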