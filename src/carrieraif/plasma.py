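"""Internal-standard calibration and plasma carrier quantification.

Quantification is classical stable-isotope-dilution: the analyte/IS peak
area ratio is interpolated on an unweighted OLS calibration line, then
corrected for the isotope skew of the carrier relative to the reference
compound used for calibration (the carrier's 13C/12C channel ratio ``x``
exceeds the reference's natural ratio ``y``, so the monitored 12C channel
under-represents the carrier by the factor ``(100+y)/(100+x)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .errors import FitError, InvalidInputError, UnitError

#: Default analyte molar mass (g/mol): PBR28.
DEFAULT_ANALYTE_MOLAR_MASS = 348.4

CONC_UNITS = ("pM", "ng/mL")


def ng_per_ml_to_pm(conc_ng_per_ml: float, molar_mass: float) -> float:
    """ng/mL -> pM.  1 ng/mL = 1e-6 g/L = (1e6 / M) pM for molar mass M."""
    if not molar_mass > 0:
        raise InvalidInputError("molar_mass must be positive")
    return conc_ng_per_ml * 1e6 / molar_mass


def pm_to_ng_per_ml(conc_pm: float, molar_mass: float) -> float:
    """pM -> ng/mL; inverse of :func:`ng_per_ml_to_pm`."""
    if not molar_mass > 0:
        raise InvalidInputError("molar_mass must be positive")
    return conc_pm * molar_mass / 1e6


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration level: nominal concentration and its area pair."""

    nominal_conc: float
    analyte_area: float
    is_area: float

    def __post_init__(self) -> None:
        if not self.nominal_conc > 0:
            raise InvalidInputError("nominal_conc must be positive")
        if not self.is_area > 0:
            raise InvalidInputError("is_area must be positive")
        if self.analyte_area < 0:
            raise InvalidInputError("analyte_area must be non-negative")

    @property
    def response(self) -> float:
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response model: area ratio = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_levels: int
    conc_unit: str = "pM"
    lloq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.conc_unit not in CONC_UNITS:
            raise UnitError(f"conc_unit must be one of {CONC_UNITS}, got {self.conc_unit!r}")
        if not self.slope > 0:
            raise FitError(f"calibration slope must be positive, got {self.slope}")
        if self.n_levels < 3:
            raise FitError("a calibration curve needs at least 3 levels")


@dataclass(frozen=True)
class PlasmaMeasurement:
    """One plasma sample's MS readout at a sampling time (min post-injection)."""

    time_min: float
    analyte_area: float
    is_area: float
    is_conc_pm: float = 0.0

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise InvalidInputError("time_min must be non-negative")
        if not self.is_area > 0:
            raise InvalidInputError("is_area must be positive")
        if self.analyte_area < 0:
            raise InvalidInputError("analyte_area must be non-negative")


@dataclass(frozen=True)
class QuantifiedSample:
    conc_pm: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def fit_calibration(
    standards: Sequence[CalibrationStandard], conc_unit: str = "pM"
) -> CalibrationCurve:
    """Unweighted OLS of analyte/IS area ratio on nominal concentration.

    Weighted regression (e.g. 1/x^2) is a deliberate non-default; the assay
    is linear over its narrow dilution series.
    """
    if len(standards) < 3:
        raise FitError("need at least 3 calibration standards")
    x = [s.nominal_conc for s in standards]
    if len(set(x)) < 3:
        raise FitError("need at least 3 distinct concentration levels")
    y = [s.response for s in standards]
    res = stats.linregress(x, y)
    if not res.slope > 0:
        raise FitError(f"calibration slope must be positive, got {res.slope}")
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_levels=len(set(x)),
        conc_unit=conc_unit,
        lloq=min(x),
    )


def quantify_sample(
    measurement: PlasmaMeasurement,
    curve: CalibrationCurve,
    molar_mass: float = DEFAULT_ANALYTE_MOLAR_MASS,
) -> QuantifiedSample:
    """Concentration (pM) of a plasma sample from its area ratio.

    Negative back-calculated concentrations (below-blank samples) are
    clamped to zero and flagged; values below the lowest calibration level
    are flagged ``below_lloq`` but reported unchanged, because late-time
    input-function points matter more than LLOQ orthodoxy.
    """
    response = measurement.analyte_area / measurement.is_area
    conc = (response - curve.intercept) / curve.slope
    flags: list[str] = []
    if conc < 0:
        flags.append("below_blank_clamped")
        conc = 0.0
    if curve.lloq is not None and conc < curve.lloq:
        flags.append("below_lloq")
    if curve.conc_unit == "ng/mL":
        conc = ng_per_ml_to_pm(conc, molar_mass)
    return QuantifiedSample(conc_pm=conc, flags=tuple(flags))


def skew_correct(conc: float, x_pct: float, y_pct: float) -> float:
    """Isotope-skew correction ``(100 + x) / (100 + y) * conc``.

    ``x`` is the carrier's 13C/12C channel ratio, ``y`` the reference
    compound's; for ``x > y`` the raw concentration is revised upward.
    """
    if x_pct <= -100 or y_pct <= -100:
        raise InvalidInputError("ratios must exceed -100 percent")
    return (100.0 + x_pct) / (100.0 + y_pct) * conc
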