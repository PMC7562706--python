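"""Arterial-input-function construction and method-comparison statistics.

Carrier concentration curves (pM) are converted to radioactivity curves
(kBq/mL) through the preparation's molar activity; radiometric curves are
built from total-activity gamma counts and radio-HPLC parent fractions, and
optionally rescaled by a preparation-specific systematic-difference factor.
Comparison statistics mirror a standard method-agreement toolkit: trapezoid
AUC, percent differences, test-retest variability (VAR), Pearson r, paired
t, and single-measures intraclass correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import FitError, InvalidInputError, UnitError

TIME_SERIES_UNITS = ("pM", "kBq/mL", "fraction")


@dataclass(frozen=True)
class TimeSeries:
    """A sampled curve: strictly increasing times (min) and values."""

    times_min: np.ndarray
    values: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times_min, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise InvalidInputError("times and values must be 1-D and equally long")
        if times.size and np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(values < 0):
            raise InvalidInputError("values must be non-negative")
        if self.unit not in TIME_SERIES_UNITS:
            raise UnitError(f"unit must be one of {TIME_SERIES_UNITS}, got {self.unit!r}")

    def __len__(self) -> int:
        return int(self.times_min.size)


def carrier_curve_to_activity(conc: TimeSeries, am_gbq_per_umol: float) -> TimeSeries:
    """pM carrier curve -> kBq/mL activity curve via A_m.

    Unit algebra: 1 pM * 1 GBq/umol = 1e-15 mol/mL * 1e15 Bq/mol = 1 Bq/mL,
    so values map as ``v * am / 1000`` to land in kBq/mL.
    """
    if conc.unit != "pM":
        raise UnitError(f"expected a pM curve, got {conc.unit!r}")
    if not am_gbq_per_umol > 0:
        raise InvalidInputError("A_m must be positive")
    return TimeSeries(conc.times_min, conc.values * am_gbq_per_umol / 1000.0, "kBq/mL")


def activity_curve_to_carrier(activity: TimeSeries, am_gbq_per_umol: float) -> TimeSeries:
    """Inverse of :func:`carrier_curve_to_activity`."""
    if activity.unit != "kBq/mL":
        raise UnitError(f"expected a kBq/mL curve, got {activity.unit!r}")
    if not am_gbq_per_umol > 0:
        raise InvalidInputError("A_m must be positive")
    return TimeSeries(activity.times_min, activity.values * 1000.0 / am_gbq_per_umol, "pM")


def radiometric_aif(total_activity: TimeSeries, parent_fraction: TimeSeries) -> TimeSeries:
    """Parent-only radiometric AIF: total activity times parent fraction.

    The parent fraction is linearly interpolated onto the activity grid;
    extrapolation beyond the measured fraction times is refused.
    """
    if total_activity.unit != "kBq/mL":
        raise UnitError("total_activity must be in kBq/mL")
    if np.any(parent_fraction.values > 1.0):
        raise InvalidInputError("parent fractions must lie in [0, 1]")
    t = total_activity.times_min
    ft, fv = parent_fraction.times_min, parent_fraction.values
    if t.min() < ft.min() or t.max() > ft.max():
        raise InvalidInputError(
            "activity times extend beyond the measured parent-fraction range; "
            "refusing to extrapolate"
        )
    f = np.interp(t, ft, fv)
    return TimeSeries(t, total_activity.values * f, "kBq/mL")


def gamma_correction_factor(pairs: Sequence[tuple[float, float]]) -> float:
    """Systematic gamma-counter/LC-MS/MS factor: geometric mean of ratios.

    The geometric mean is the maximum-likelihood estimator of a constant
    multiplicative bias under lognormal measurement noise; a corrected
    gamma value is ``gamma / factor``.
    """
    if not pairs:
        raise InvalidInputError("need at least one (gamma, lcms) pair")
    logs = []
    for g, l in pairs:
        if not (g > 0 and l > 0):
            raise InvalidInputError(f"pair values must be positive, got ({g}, {l})")
        logs.append(math.log(g / l))
    return math.exp(sum(logs) / len(logs))


def apply_gamma_correction(ts: TimeSeries, factor: float) -> TimeSeries:
    if not factor > 0:
        raise InvalidInputError("correction factor must be positive")
    return TimeSeries(ts.times_min, ts.values / factor, ts.unit)


def auc_trapezoid(ts: TimeSeries) -> float:
    """Trapezoid AUC over the observed time range; no extrapolation."""
    if len(ts) < 2:
        raise InvalidInputError("need at least two points for an AUC")
    return float(np.trapezoid(ts.values, ts.times_min))


def percent_lower(a: float, reference: float) -> float:
    """How much lower ``a`` is than ``reference``: 100 * (ref - a) / ref."""
    if not reference > 0:
        raise InvalidInputError("reference must be positive")
    return 100.0 * (reference - a) / reference


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference of ``value`` from ``reference``."""
    if not reference > 0:
        raise InvalidInputError("reference must be positive")
    return 100.0 * (value - reference) / reference


def var_percent(a: float, b: float) -> float:
    """Test-retest variability: absolute difference over the pair mean, %."""
    if a < 0 or b < 0:
        raise InvalidInputError("values must be non-negative")
    mean = (a + b) / 2.0
    if mean == 0:
        raise InvalidInputError("VAR undefined when both values are zero")
    return 100.0 * abs(a - b) / mean


def _mean_squares(a: np.ndarray, b: np.ndarray):
    X = np.column_stack([a, b])
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_tot - ss_rows) / (n * (k - 1))
    return n, k, msr, msc, mse, msw


def icc_single_measures(
    pairs: Sequence[tuple[float, float]],
    model: Literal["one_way", "two_way_agreement"] = "one_way",
) -> float:
    """Single-measures intraclass correlation of paired measurements.

    ``one_way`` is ICC(1,1): one-way random-effects, where the rater/method
    effect is absorbed into within-subject variance, so a constant offset
    between methods depresses the coefficient.  ``two_way_agreement`` is
    ICC(2,1) (two-way random, absolute agreement).  Both are sensitive to
    systematic differences; Pearson r is not.
    """
    if len(pairs) < 3:
        raise FitError("ICC needs at least 3 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.array_equal(a, b):
        # Identical series: perfect agreement by convention.
        return 1.0
    n, k, msr, msc, mse, msw = _mean_squares(a, b)
    if model == "one_way":
        denom = msr + (k - 1) * msw
        if denom == 0:
            raise FitError("degenerate input: zero total variance")
        return float((msr - msw) / denom)
    if model == "two_way_agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise FitError("degenerate input: zero total variance")
        return float((msr - mse) / denom)
    raise InvalidInputError(f"unknown ICC model {model!r}")


def icc_absolute_agreement(pairs: Sequence[tuple[float, float]]) -> float:
    """ICC(2,1): two-way random-effects, absolute agreement, single measures."""
    return icc_single_measures(pairs, model="two_way_agreement")


def paired_t(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Two-sided paired-samples t test; returns (t, p) with n-1 df."""
    if len(pairs) < 2:
        raise InvalidInputError("paired t needs at least 2 pairs")
    d = np.asarray([p[0] - p[1] for p in pairs], dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise FitError("zero variance of non-zero differences")
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2.0 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def pearson(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson r; NaN (not an error) for zero-variance input, which arises
    legitimately in noiseless simulations where every subject is identical."""
    if len(pairs) < 2:
        raise InvalidInputError("Pearson r needs at least 2 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        return float(stats.pearsonr(a, b).statistic)


@dataclass(frozen=True)
class PairStats:
    """Agreement statistics between one pair of AUC series."""

    var_pct: float
    pearson_r: float
    icc: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class MethodComparison:
    """AUC-level comparison of the carrier-derived AIF against both
    radiometric variants, mirroring a per-study summary table."""

    auc_lcms: float
    auc_rad_uncorrected: float
    auc_rad_corrected: float
    pct_diff_uncorrected: float
    pct_diff_corrected: float
    uncorrected: PairStats
    corrected: PairStats
    n_subjects: int


def _pair_stats(lcms: np.ndarray, other: np.ndarray, icc_model: str) -> PairStats:
    pairs = list(zip(lcms, other))
    t, p = paired_t(pairs)
    return PairStats(
        var_pct=float(np.mean([var_percent(a, b) for a, b in pairs])),
        pearson_r=pearson(pairs),
        icc=icc_single_measures(pairs, model=icc_model),
        t_stat=t,
        p_value=p,
    )


def compare_aucs(
    auc_lcms: Sequence[float],
    auc_rad_uncorrected: Sequence[float],
    auc_rad_corrected: Sequence[float],
    icc_model: Literal["one_way", "two_way_agreement"] = "one_way",
) -> MethodComparison:
    """Summarize per-subject AUC triples into a method comparison."""
    lc = np.asarray(auc_lcms, dtype=float)
    ra = np.asarray(auc_rad_uncorrected, dtype=float)
    rb = np.asarray(auc_rad_corrected, dtype=float)
    if not (lc.size == ra.size == rb.size):
        raise InvalidInputError("AUC series must be equally long")
    if lc.size < 3:
        raise FitError("method comparison needs at least 3 subjects")
    return MethodComparison(
        auc_lcms=float(lc.mean()),
        auc_rad_uncorrected=float(ra.mean()),
        auc_rad_corrected=float(rb.mean()),
        pct_diff_uncorrected=percent_lower(float(lc.mean()), float(ra.mean())),
        pct_diff_corrected=percent_lower(float(lc.mean()), float(rb.mean())),
        uncorrected=_pair_stats(lc, ra, icc_model),
        corrected=_pair_stats(lc, rb, icc_model),
        n_subjects=int(lc.size),
    )
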