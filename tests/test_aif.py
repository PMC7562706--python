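import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benchmarks import AUC_SUMMARY, DOSE_RADIOACTIVITY, PLASMA_CONCENTRATIONS, SUBJECT_AUCS
from carrieraif.aif import (
    TimeSeries,
    activity_curve_to_carrier,
    apply_gamma_correction,
    auc_trapezoid,
    carrier_curve_to_activity,
    compare_aucs,
    gamma_correction_factor,
    icc_absolute_agreement,
    icc_single_measures,
    paired_t,
    pearson,
    percent_difference,
    percent_lower,
    radiometric_aif,
    var_percent,
)
from carrieraif.errors import FitError, InvalidInputError, UnitError


class TestTimeSeries:
    def test_validation(self):
        with pytest.raises(InvalidInputError):
            TimeSeries([1.0, 1.0], [0.0, 0.0], "pM")
        with pytest.raises(InvalidInputError):
            TimeSeries([1.0, 2.0], [0.0, -1.0], "pM")
        with pytest.raises(UnitError):
            TimeSeries([1.0, 2.0], [0.0, 1.0], "furlongs")


class TestCarrierActivityConversion:
    def test_unit_algebra_example(self):
        # 140.1 pM at 385.9 GBq/umol: 140.1 * 385.9 = 54064.6 Bq/mL,
        # i.e. 54.06 kBq/mL.  (1 pM x 1 GBq/umol = 1 Bq/mL exactly.)
        ts = TimeSeries([2.5], [140.1], "pM")
        out = carrier_curve_to_activity(ts, 385.9)
        assert out.unit == "kBq/mL"
        assert out.values[0] == pytest.approx(54.06459, rel=1e-9)

    def test_zero_maps_to_zero(self):
        out = carrier_curve_to_activity(TimeSeries([1.0], [0.0], "pM"), 500.0)
        assert out.values[0] == 0.0

    def test_round_trip(self):
        ts = TimeSeries([1.0, 2.0, 3.0], [10.0, 5.0, 2.5], "pM")
        back = activity_curve_to_carrier(carrier_curve_to_activity(ts, 385.9), 385.9)
        np.testing.assert_allclose(back.values, ts.values, rtol=1e-12)

    def test_unit_mismatch(self):
        with pytest.raises(UnitError):
            carrier_curve_to_activity(TimeSeries([1.0], [1.0], "kBq/mL"), 385.9)


class TestRadiometricAif:
    def test_unit_fraction_is_identity(self):
        total = TimeSeries([1.0, 2.0, 3.0], [30.0, 20.0, 10.0], "kBq/mL")
        pf = TimeSeries([0.5, 3.5], [1.0, 1.0], "fraction")
        out = radiometric_aif(total, pf)
        np.testing.assert_allclose(out.values, total.values)

    def test_half_fraction_halves(self):
        total = TimeSeries([1.0, 2.0], [30.0, 20.0], "kBq/mL")
        pf = TimeSeries([0.0, 5.0], [0.5, 0.5], "fraction")
        np.testing.assert_allclose(radiometric_aif(total, pf).values, [15.0, 10.0])

    def test_fraction_above_one_rejected(self):
        total = TimeSeries([1.0, 2.0], [30.0, 20.0], "kBq/mL")
        with pytest.raises(InvalidInputError):
            radiometric_aif(total, TimeSeries([0.0, 5.0], [1.2, 0.5], "fraction"))

    def test_no_extrapolation(self):
        total = TimeSeries([1.0, 10.0], [30.0, 20.0], "kBq/mL")
        pf = TimeSeries([2.0, 5.0], [0.9, 0.5], "fraction")
        with pytest.raises(InvalidInputError):
            radiometric_aif(total, pf)


class TestGammaCorrectionFactor:
    def test_single_benchmark_pair(self):
        factor = gamma_correction_factor([(2349.0, 1726.0)])
        assert factor == pytest.approx(1.361, abs=5e-4)

    def test_applies_to_late_sample(self):
        factor = gamma_correction_factor([(2349.0, 1726.0)])
        assert 29.81 / factor == pytest.approx(21.90, abs=5e-3)

    def test_identity_for_equal_pairs(self):
        assert gamma_correction_factor([(5.0, 5.0), (7.0, 7.0)]) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            gamma_correction_factor([(1.0, 0.0)])

    def test_benchmark_ratio_constant_within_preparation(self):
        # Uncorrected/corrected ratio is constant across timepoints of a
        # preparation; factors land near 1.361 / 1.322 / 1.290.
        expected = {138.6: 1.361, 200.4: 1.322, 385.9: 1.290}
        for am, rows in PLASMA_CONCENTRATIONS.items():
            ratios = [a / b for (_, a, b, _) in rows]
            assert max(ratios) / min(ratios) < 1.001
            assert np.mean(ratios) == pytest.approx(expected[am], abs=2e-3)


class TestAuc:
    def test_constant(self):
        ts = TimeSeries(np.linspace(0, 10, 11), np.ones(11), "kBq/mL")
        assert auc_trapezoid(ts) == pytest.approx(10.0, rel=1e-12)

    def test_line(self):
        assert auc_trapezoid(TimeSeries([0.0, 2.0], [0.0, 2.0], "kBq/mL")) == pytest.approx(2.0)

    def test_dense_exponential_closed_form(self):
        t = np.linspace(0.0, 90.0, 1000)
        ts = TimeSeries(t, np.exp(-t / 10.0), "kBq/mL")
        analytic = 10.0 * (1.0 - math.exp(-9.0))
        assert auc_trapezoid(ts) == pytest.approx(analytic, rel=1e-4)

    def test_additive_over_intervals_and_collinear_insertion(self):
        t = np.array([0.0, 1.0, 2.0, 4.0])
        v = np.array([1.0, 3.0, 2.0, 0.5])
        full = auc_trapezoid(TimeSeries(t, v, "kBq/mL"))
        left = auc_trapezoid(TimeSeries(t[:3], v[:3], "kBq/mL"))
        right = auc_trapezoid(TimeSeries(t[2:], v[2:], "kBq/mL"))
        assert full == pytest.approx(left + right, rel=1e-12)
        # insert the midpoint of the last segment (collinear)
        t2 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        v2 = np.array([1.0, 3.0, 2.0, 1.25, 0.5])
        assert auc_trapezoid(TimeSeries(t2, v2, "kBq/mL")) == pytest.approx(full, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidInputError):
            auc_trapezoid(TimeSeries([1.0], [1.0], "kBq/mL"))


class TestPercentStats:
    def test_percent_lower_benchmarks(self):
        assert round(percent_lower(368.0, 536.0)) == 31
        assert round(percent_lower(368.0, 399.0)) == 8
        assert percent_lower(5.0, 5.0) == 0.0

    def test_percent_difference_dose_table(self):
        lcms, gamma = DOSE_RADIOACTIVITY[1][2], DOSE_RADIOACTIVITY[1][3]
        assert percent_difference(gamma, lcms) == pytest.approx(32.2, abs=0.05)

    def test_var_percent(self):
        assert var_percent(5.0, 5.0) == 0.0
        assert var_percent(328.0, 470.0) == pytest.approx(35.6, abs=0.05)
        assert var_percent(3.0, 7.0) == var_percent(7.0, 3.0)

    def test_var_both_zero(self):
        with pytest.raises(InvalidInputError):
            var_percent(0.0, 0.0)

    @given(
        st.floats(min_value=10.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=0.05),
    )
    @settings(max_examples=50, deadline=None)
    def test_percent_lower_and_var_agree_to_first_order(self, ref, rel):
        a = ref * (1.0 - rel)
        assert abs(percent_lower(a, ref) - var_percent(a, ref)) < 100 * rel**2 + 1e-9


def _icc_oracle_one_way(a, b):
    # Brute-force one-way ANOVA decomposition, coded independently of the
    # implementation under test.
    X = np.column_stack([a, b]).astype(float)
    n, k = X.shape
    grand = X.mean()
    ms_between = k * sum((row.mean() - grand) ** 2 for row in X) / (n - 1)
    ms_within = sum((x - row.mean()) ** 2 for row in X for x in row) / (n * (k - 1))
    return (ms_between - ms_within) / (ms_between + (k - 1) * ms_within)


class TestIcc:
    def test_identical_series(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        assert icc_single_measures(pairs) == 1.0
        assert icc_absolute_agreement(pairs) == 1.0

    def test_small_example_against_anova_oracle(self):
        a = [9.0, 6.0, 8.0, 7.0]
        b = [2.0, 1.0, 4.0, 1.0]
        pairs = list(zip(a, b))
        assert icc_single_measures(pairs, model="one_way") == pytest.approx(
            _icc_oracle_one_way(a, b), rel=1e-12
        )

    def test_two_way_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.uniform(10, 20, size=12)
        b = a * 1.1 + rng.normal(0, 0.5, size=12)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "rater": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([a, b]),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        expected2 = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        expected1 = float(table.loc[table["Type"] == "ICC(1,1)", "ICC"].iloc[0])
        pairs = list(zip(a, b))
        assert icc_absolute_agreement(pairs) == pytest.approx(expected2, abs=1e-9)
        assert icc_single_measures(pairs, model="one_way") == pytest.approx(expected1, abs=1e-9)

    def test_offset_lowers_icc_but_not_pearson(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(100, 200, size=10)
        base = list(zip(a, a))
        shifted = list(zip(a, a + 50.0))
        for model in ("one_way", "two_way_agreement"):
            assert icc_single_measures(shifted, model=model) < 1.0
        assert pearson(shifted) == pytest.approx(1.0, rel=1e-12)

    def test_needs_three_pairs(self):
        with pytest.raises(FitError):
            icc_single_measures([(1.0, 2.0), (2.0, 3.0)])


class TestPairedTAndPearson:
    def test_identical_series(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        t, p = paired_t(pairs)
        assert t == 0.0 and p == 1.0

    def test_linear_pairs_pearson(self):
        pairs = [(x, 2 * x + 1) for x in (1.0, 2.0, 3.0, 4.0)]
        assert pearson(pairs) == pytest.approx(1.0)

    def test_five_pair_hand_computation(self):
        a = [10.0, 12.0, 9.0, 11.0, 13.0]
        b = [8.0, 11.0, 9.5, 9.0, 12.0]
        d = np.array(a) - np.array(b)
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        t, p = paired_t(list(zip(a, b)))
        assert t == pytest.approx(expected_t, rel=1e-12)
        assert 0.0 < p < 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(FitError):
            paired_t([(1.0, 2.0), (2.0, 3.0), (3.0, 4.0)])


@pytest.fixture(scope="module")
def comparison():
    lc = [v[0] for v in SUBJECT_AUCS.values()]
    ra = [v[1] for v in SUBJECT_AUCS.values()]
    rb = [v[2] for v in SUBJECT_AUCS.values()]
    return compare_aucs(lc, ra, rb, icc_model="one_way")


class TestBenchmarkStudySummary:
    """Recompute the eight-subject AUC comparison from its per-subject rows
    and check every published summary statistic."""

    def test_means(self, comparison):
        assert round(comparison.auc_lcms) == 368
        assert round(comparison.auc_rad_uncorrected) == 536
        assert comparison.auc_rad_corrected == pytest.approx(
            AUC_SUMMARY["mean_rad_corrected"], abs=1.0
        )

    def test_percent_lower(self, comparison):
        assert round(comparison.pct_diff_uncorrected) == AUC_SUMMARY["pct_lower_uncorrected"]
        assert round(comparison.pct_diff_corrected) == AUC_SUMMARY["pct_lower_corrected"]

    def test_var(self, comparison):
        assert comparison.uncorrected.var_pct == pytest.approx(
            AUC_SUMMARY["var_uncorrected"], abs=0.5
        )
        assert comparison.corrected.var_pct == pytest.approx(
            AUC_SUMMARY["var_corrected"], abs=0.2
        )

    def test_pearson(self, comparison):
        assert comparison.uncorrected.pearson_r == pytest.approx(
            AUC_SUMMARY["pearson_uncorrected"], abs=0.005
        )
        assert comparison.corrected.pearson_r == pytest.approx(
            AUC_SUMMARY["pearson_corrected"], abs=0.005
        )

    def test_icc(self, comparison):
        assert comparison.uncorrected.icc == pytest.approx(
            AUC_SUMMARY["icc_uncorrected"], abs=0.005
        )
        assert comparison.corrected.icc == pytest.approx(
            AUC_SUMMARY["icc_corrected"], abs=0.01
        )

    def test_paired_t(self, comparison):
        assert comparison.uncorrected.t_stat == pytest.approx(
            AUC_SUMMARY["t_uncorrected"], abs=0.1
        )
        assert comparison.corrected.t_stat == pytest.approx(
            AUC_SUMMARY["t_corrected"], abs=0.1
        )
        assert comparison.uncorrected.p_value < 0.001
        assert comparison.corrected.p_value < 0.001

    def test_gamma_correction_applied(self):
        factor = gamma_correction_factor([(2349.0, 1726.0)])
        corrected = apply_gamma_correction(
            TimeSeries([59.98], [29.81], "kBq/mL"), factor
        )
        assert corrected.values[0] == pytest.approx(21.90, abs=5e-3)
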