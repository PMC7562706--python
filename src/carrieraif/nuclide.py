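"""Nuclide constants, radioactive-decay arithmetic, and first-order
natural-abundance isotopologue ratios for MS/MS product ions.

Activities are in Bq, amounts in mol, times in seconds unless a name says
otherwise.  The carrier-free molar activity ``A_m* = (ln 2 / t_half) * N_A``
is always *computed* from the half-life rather than hard-coded, so that a
half-life override propagates everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import InvalidInputError

LN2 = math.log(2.0)

#: CODATA-exact Avogadro constant (1/mol).
AVOGADRO = 6.02214076e23

#: Default carbon-11 half-life in seconds (20.4 min).
C11_HALF_LIFE_S = 20.4 * 60.0

DecayDirection = Literal["back_to_reference", "forward"]


def carrier_free_molar_activity(half_life_s: float, avogadro: float = AVOGADRO) -> float:
    """Theoretical maximum molar activity of a pure radionuclide, Bq/mol.

    Equals ``(ln 2 / half_life_s) * avogadro``: the activity of one mole of
    atoms that are all radioactive.
    """
    if not half_life_s > 0:
        raise InvalidInputError(f"half_life_s must be positive, got {half_life_s}")
    return (LN2 / half_life_s) * avogadro


@dataclass(frozen=True)
class NuclideConstants:
    """Physical constants of one radionuclide.

    The fields are internally consistent by construction when created via
    :meth:`from_half_life`; ``__post_init__`` re-checks consistency so that
    hand-built instances cannot silently disagree.
    """

    half_life_s: float
    decay_constant_per_s: float
    avogadro: float
    am_star_bq_per_mol: float

    def __post_init__(self) -> None:
        for name in ("half_life_s", "decay_constant_per_s", "avogadro", "am_star_bq_per_mol"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidInputError(f"{name} must be strictly positive, got {value}")
        lam = LN2 / self.half_life_s
        if abs(self.decay_constant_per_s - lam) > 1e-9 * lam:
            raise InvalidInputError("decay_constant_per_s inconsistent with half_life_s")
        am_star = self.decay_constant_per_s * self.avogadro
        if abs(self.am_star_bq_per_mol - am_star) > 1e-9 * am_star:
            raise InvalidInputError("am_star_bq_per_mol inconsistent with decay constant")

    @classmethod
    def from_half_life(cls, half_life_s: float, avogadro: float = AVOGADRO) -> "NuclideConstants":
        lam = LN2 / half_life_s
        return cls(
            half_life_s=half_life_s,
            decay_constant_per_s=lam,
            avogadro=avogadro,
            am_star_bq_per_mol=carrier_free_molar_activity(half_life_s, avogadro),
        )


#: Carbon-11 with the default 20.4 min half-life.
CARBON11 = NuclideConstants.from_half_life(C11_HALF_LIFE_S)


def decay_correct(
    activity_bq: float,
    elapsed_s: float,
    constants: NuclideConstants,
    direction: DecayDirection = "back_to_reference",
) -> float:
    """Decay-correct an activity over ``elapsed_s`` seconds.

    ``back_to_reference`` answers "what was the activity at the reference
    time, elapsed_s before the measurement" (multiplies by ``exp(+lambda t)``);
    ``forward`` propagates a known activity into the future
    (multiplies by ``exp(-lambda t)``).
    """
    if activity_bq < 0:
        raise InvalidInputError(f"activity must be non-negative, got {activity_bq}")
    if elapsed_s < 0:
        raise InvalidInputError(f"elapsed_s must be non-negative, got {elapsed_s}")
    if direction == "back_to_reference":
        return activity_bq * math.exp(constants.decay_constant_per_s * elapsed_s)
    if direction == "forward":
        return activity_bq * math.exp(-constants.decay_constant_per_s * elapsed_s)
    raise InvalidInputError(f"unknown decay direction: {direction!r}")


def activity_to_amount(activity_bq: float, constants: NuclideConstants) -> float:
    """Moles of radioactive atoms carrying ``activity_bq`` of activity."""
    if activity_bq < 0:
        raise InvalidInputError(f"activity must be non-negative, got {activity_bq}")
    return activity_bq / (constants.decay_constant_per_s * constants.avogadro)


def amount_to_activity(amount_mol: float, constants: NuclideConstants) -> float:
    """Exact inverse of :func:`activity_to_amount`."""
    if amount_mol < 0:
        raise InvalidInputError(f"amount must be non-negative, got {amount_mol}")
    return amount_mol * constants.decay_constant_per_s * constants.avogadro


@dataclass(frozen=True)
class ProductIonComposition:
    """Elemental composition of one monitored product ion."""

    n_carbon: int = 0
    n_hydrogen: int = 0
    n_nitrogen: int = 0
    n_oxygen: int = 0
    contains_label_site: bool = False

    def __post_init__(self) -> None:
        for name in ("n_carbon", "n_hydrogen", "n_nitrogen", "n_oxygen"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.contains_label_site and self.n_carbon < 1:
            raise InvalidInputError("a label-site-containing ion needs n_carbon >= 1")


@dataclass(frozen=True)
class IsotopeAbundances:
    """Per-atom heavy/light isotope ratios, in percent.

    Defaults follow standard terrestrial reference abundances expressed as
    heavy-to-light ratios (13C/12C ~ 1.08%, 2H/1H ~ 0.0115%, 15N/14N ~ 0.365%,
    17O/16O ~ 0.038%); every value is overridable from configuration.
    """

    r13_pct: float = 1.082
    r2h_pct: float = 0.0115
    r15n_pct: float = 0.365
    r17o_pct: float = 0.038

    def __post_init__(self) -> None:
        for name in ("r13_pct", "r2h_pct", "r15n_pct", "r17o_pct"):
            value = getattr(self, name)
            if not (0.0 <= value <= 5.0):
                raise InvalidInputError(f"{name} must lie in [0, 5] percent, got {value}")


def natural_m1_ratio(
    composition: ProductIonComposition,
    abundances: IsotopeAbundances = IsotopeAbundances(),
) -> float:
    """First-order natural M+1/M ratio of a product ion, in percent.

    Sums single-substitution contributions (13C, 2H, 15N, 17O) over the atom
    counts; multiple-substitution terms are second order and ignored.
    """
    return (
        composition.n_carbon * abundances.r13_pct
        + composition.n_hydrogen * abundances.r2h_pct
        + composition.n_nitrogen * abundances.r15n_pct
        + composition.n_oxygen * abundances.r17o_pct
    )
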