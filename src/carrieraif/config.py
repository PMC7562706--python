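"""Structured configuration for the pipeline, loadable from YAML."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import SchemaError
from .nuclide import AVOGADRO, IsotopeAbundances, NuclideConstants
from .synthetic import StudySimConfig


class ConstantsConfig(BaseModel):
    """Nuclide half-life and isotope-abundance overrides (flat keys)."""

    half_life_min: float = Field(default=20.4, gt=0.0)
    r13_pct: float = Field(default=1.082, ge=0.0, le=5.0)
    r2h_pct: float = Field(default=0.0115, ge=0.0, le=5.0)
    r15n_pct: float = Field(default=0.365, ge=0.0, le=5.0)
    r17o_pct: float = Field(default=0.038, ge=0.0, le=5.0)


class StudyConfig(BaseModel):
    """Top-level pipeline configuration.

    ``natural_ratio_pct`` is the reference compound's measured 13C/12C
    channel ratio (the product-ion M+1 ratio), used both for the A* term in
    molar-activity computation and as ``y`` in the skew correction.
    """

    constants: ConstantsConfig = ConstantsConfig()
    analyte_molar_mass: float = Field(default=348.4, gt=0.0)
    natural_ratio_pct: float = Field(default=9.16, gt=0.0)
    icc_model: Literal["one_way", "two_way_agreement"] = "one_way"
    correction_source: Literal["vials", "aif_pairs"] = "vials"
    simulation: StudySimConfig = StudySimConfig()
    seed: int = 1

    def nuclide_constants(self) -> NuclideConstants:
        return NuclideConstants.from_half_life(self.constants.half_life_min * 60.0, AVOGADRO)

    def abundances(self) -> IsotopeAbundances:
        c = self.constants
        return IsotopeAbundances(
            r13_pct=c.r13_pct, r2h_pct=c.r2h_pct, r15n_pct=c.r15n_pct, r17o_pct=c.r17o_pct
        )


def default_config() -> StudyConfig:
    return StudyConfig()


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML config; errors name the offending keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    try:
        return StudyConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise SchemaError(f"invalid configuration ({path}): bad keys: {keys}\n{exc}") from exc


def config_hash(cfg: StudyConfig) -> str:
    """Stable content hash of a configuration, for provenance records."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
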