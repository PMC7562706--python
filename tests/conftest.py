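import pytest

from carrieraif.config import StudyConfig
from carrieraif.synthetic import (
    CalibrationConfig,
    ProductionConfig,
    StudySimConfig,
    SubjectConfig,
)


def zero_noise_sim_config(**overrides) -> StudySimConfig:
    base = dict(
        n_subjects=8,
        production=ProductionConfig(ms_area_cv=0.0),
        calibration=CalibrationConfig(
            conc_unit="pM", sensitivity=1e-3, top_conc=3000.0, cv=0.0
        ),
        subject=SubjectConfig(gamma_cv=0.0, ms_cv=0.0),
        gamma_bias_sd=0.0,
        between_subject_sd=0.0,
    )
    base.update(overrides)
    return StudySimConfig(**base)


@pytest.fixture
def zero_noise_config() -> StudyConfig:
    """Pipeline config whose generator is fully deterministic and noiseless."""
    return StudyConfig(simulation=zero_noise_sim_config(), seed=7)


@pytest.fixture
def noisy_config() -> StudyConfig:
    """Default, paper-scale noise everywhere."""
    return StudyConfig(seed=11)
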