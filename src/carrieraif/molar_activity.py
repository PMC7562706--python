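"""Molar activity (A_m) from isotopologue peak areas.

The dose assay monitors up to three isotopologue channels of the tracer's
product ion: the radioactive species (11C at the label site), the light
carrier (12C), and the M+1 carrier channel (13C at the label site plus the
natural single-heavy-atom species of the 12C carrier).

A_m is computed as ``A* / (A + A*) * A_m*`` where

* ``A*`` is the radioactive-species signal, inflated by the natural M+1
  ratio to account for radioactive molecules carrying an additional natural
  heavy atom elsewhere (those fall in an unmonitored channel),
* ``A``  is the total carrier signal (12C + 13C channels; in pair mode the
  12C area is reconstructed from the 13C area via the carrier's measured
  13C/12C channel ratio),
* ``A_m*`` is the carrier-free molar activity of the nuclide.

The natural M+1 inflation of ``A*`` deliberately uses the *reference
compound's* natural ratio, not the enriched carrier ratio: enrichment sits
at the label site, which in radioactive molecules is occupied by 11C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from scipy import stats

from .errors import FitError, InvalidInputError
from .nuclide import CARBON11, NuclideConstants

#: 1 Bq/mol expressed in GBq/umol.
BQ_PER_MOL_TO_GBQ_PER_UMOL = 1e-15


def am_star_gbq_per_umol(constants: NuclideConstants = CARBON11) -> float:
    """Carrier-free molar activity in the package's canonical A_m unit."""
    return constants.am_star_bq_per_mol * BQ_PER_MOL_TO_GBQ_PER_UMOL


@dataclass(frozen=True)
class IsotopologueAreas:
    """Integrated peak areas of one dose-analysis injection.

    ``area_12c`` is ``None`` for pair-mode acquisitions where the carrier
    12C channel was not monitored (e.g. to avoid detector saturation).
    """

    area_11c: float
    area_13c: float
    area_12c: Optional[float] = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.area_11c < 0 or self.area_13c < 0:
            raise InvalidInputError("peak areas must be non-negative")
        if self.area_12c is not None:
            if self.area_12c < 0:
                raise InvalidInputError("peak areas must be non-negative")
            if self.area_13c >= self.area_12c > 0:
                raise InvalidInputError(
                    "area_13c must be smaller than area_12c for a real carrier"
                )


@dataclass(frozen=True)
class CarrierIsotopeRatio:
    """13C-channel to 12C-channel area ratio, percent.

    Zero is admitted (a hypothetical heavy-free carrier) so that the ratio
    operation is total; consumers that divide by the ratio require it to be
    strictly positive.
    """

    ratio_pct: float
    source: Literal["reference_compound", "dose_carrier"] = "dose_carrier"

    def __post_init__(self) -> None:
        if self.ratio_pct < 0:
            raise InvalidInputError(f"ratio_pct must be non-negative, got {self.ratio_pct}")


@dataclass(frozen=True)
class MolarActivityResult:
    """Replicate-aggregated A_m of one preparation."""

    am_gbq_per_umol: float
    sd: float
    n: int
    mode: Literal["pair", "triad"]
    per_replicate: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class EnrichmentLine:
    """OLS line of carrier 13C/12C ratio (%) against A_m (GBq/umol)."""

    slope: float
    intercept_pct: float
    pearson_r: float
    n: int


def ratio_13_12(area_13c: float, area_12c: float) -> CarrierIsotopeRatio:
    """Carrier isotope-channel ratio: ``100 * area_13c / area_12c``."""
    if area_13c < 0:
        raise InvalidInputError("area_13c must be non-negative")
    if not area_12c > 0:
        raise InvalidInputError(f"area_12c must be positive, got {area_12c}")
    return CarrierIsotopeRatio(ratio_pct=100.0 * area_13c / area_12c)


def _am_from_signals(
    astar_signal: float, carrier_signal: float, constants: NuclideConstants
) -> float:
    total = carrier_signal + astar_signal
    if total <= 0:
        raise InvalidInputError("total isotopologue signal must be positive")
    return astar_signal / total * am_star_gbq_per_umol(constants)


def am_from_pair(
    area_11c: float,
    area_13c: float,
    carrier_ratio: CarrierIsotopeRatio,
    natural_ratio_pct: float,
    constants: NuclideConstants = CARBON11,
) -> float:
    """A_m (GBq/umol) from the 11C and 13C channels only.

    The carrier 12C area is reconstructed as
    ``area_13c * 100 / carrier_ratio.ratio_pct``.
    """
    if area_11c < 0:
        raise InvalidInputError("area_11c must be non-negative")
    if not area_13c > 0:
        raise InvalidInputError("area_13c must be positive in pair mode")
    if natural_ratio_pct < 0:
        raise InvalidInputError("natural_ratio_pct must be non-negative")
    if not carrier_ratio.ratio_pct > 0:
        raise InvalidInputError("pair mode needs a strictly positive carrier ratio")
    area_12c_est = area_13c * 100.0 / carrier_ratio.ratio_pct
    carrier_signal = area_12c_est + area_13c
    astar_signal = area_11c * (1.0 + natural_ratio_pct / 100.0)
    return _am_from_signals(astar_signal, carrier_signal, constants)


def am_from_triad(
    area_11c: float,
    area_12c: float,
    area_13c: float,
    natural_ratio_pct: float,
    constants: NuclideConstants = CARBON11,
) -> float:
    """A_m (GBq/umol) from all three monitored isotopologue channels."""
    if area_11c < 0 or area_13c < 0:
        raise InvalidInputError("peak areas must be non-negative")
    if not area_12c > 0:
        raise InvalidInputError(f"area_12c must be positive, got {area_12c}")
    if natural_ratio_pct < 0:
        raise InvalidInputError("natural_ratio_pct must be non-negative")
    carrier_signal = area_12c + area_13c
    astar_signal = area_11c * (1.0 + natural_ratio_pct / 100.0)
    return _am_from_signals(astar_signal, carrier_signal, constants)


def molar_activity_from_replicates(
    replicates: Sequence[IsotopologueAreas],
    natural_ratio_pct: float,
    constants: NuclideConstants = CARBON11,
    carrier_ratio: Optional[CarrierIsotopeRatio] = None,
) -> MolarActivityResult:
    """Per-replicate A_m, aggregated as mean +/- SD.

    Triad mode is used when every replicate carries a 12C area; otherwise
    pair mode is used and ``carrier_ratio`` is required.  No outlier
    rejection is applied.
    """
    if not replicates:
        raise InvalidInputError("at least one replicate is required")
    triad = all(r.area_12c is not None for r in replicates)
    values = []
    for r in replicates:
        if triad:
            values.append(
                am_from_triad(r.area_11c, r.area_12c, r.area_13c, natural_ratio_pct, constants)
            )
        else:
            if carrier_ratio is None:
                raise InvalidInputError("pair mode requires a measured carrier_ratio")
            values.append(
                am_from_pair(r.area_11c, r.area_13c, carrier_ratio, natural_ratio_pct, constants)
            )
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return MolarActivityResult(
        am_gbq_per_umol=mean,
        sd=sd,
        n=n,
        mode="triad" if triad else "pair",
        per_replicate=tuple(values),
    )


def radioactivity_from_carrier(carrier_pmol: float, am_gbq_per_umol: float) -> float:
    """Radioactivity (kBq) of a sample from its carrier amount and A_m.

    Unit algebra: pmol * GBq/umol = 1e-12 mol * 1e15 Bq/mol * 1e-3 kBq/Bq = kBq.
    """
    if carrier_pmol < 0 or am_gbq_per_umol < 0:
        raise InvalidInputError("carrier amount and A_m must be non-negative")
    return carrier_pmol * am_gbq_per_umol


def carrier_from_radioactivity(kbq: float, am_gbq_per_umol: float) -> float:
    """Exact inverse of :func:`radioactivity_from_carrier` (pmol)."""
    if kbq < 0:
        raise InvalidInputError("radioactivity must be non-negative")
    if not am_gbq_per_umol > 0:
        raise InvalidInputError(f"A_m must be positive, got {am_gbq_per_umol}")
    return kbq / am_gbq_per_umol


def fit_enrichment_line(points: Sequence[tuple[float, float]]) -> EnrichmentLine:
    """OLS fit of carrier isotope ratio (%) on A_m across preparations."""
    if len(points) < 2:
        raise FitError("need at least two (A_m, ratio) points")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if max(x) == min(x):
        raise FitError("A_m values are degenerate; cannot fit a line")
    res = stats.linregress(x, y)
    return EnrichmentLine(
        slope=float(res.slope),
        intercept_pct=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=len(points),
    )
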