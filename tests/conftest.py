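import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psoriastat.cohort import GeneratorConfig, generate_cohort
from psoriastat.instruments import (
    AREAS,
    DigitFlags,
    PaseAnswers,
    PatientRecord,
    PsaaItems,
    PwesiArea,
    RegionAssessment,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    patient_id: str = "P1",
    extent: float = 0.0,
    severity: int = 0,
    arthritis: int = 0,
    pwesi_level: int = 0,
    pase_answer: int = 1,
    history: int = 0,
    exam: int = 0,
    nail: int = 0,
    joint: int = 0,
    pga: int = 0,
    global_item: int = 0,
) -> PatientRecord:
    """A homogeneous patient record; defaults give the all-minimal patient."""
    return PatientRecord(
        patient_id=patient_id,
        assessor_id="A1",
        regions=[
            RegionAssessment(a, extent, severity, severity, severity, arthritis)
            for a in AREAS
        ],
        pwesi=[PwesiArea(a, pwesi_level, pwesi_level) for a in AREAS],
        pase=PaseAnswers(symptom=[pase_answer] * 7, function=[pase_answer] * 8),
        psaa=PsaaItems(history=[history] * 2, exam=[exam] * 6),
        nails=DigitFlags([nail] * 10, "nail"),
        joints=DigitFlags([joint] * 10, "joint"),
        global_pga=pga,
        quality_of_life=global_item,
        pain=global_item,
        itch=global_item,
        toe_nail_any=nail,
        toe_joint_any=joint,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """180 patients, default (independent-latent) generator."""
    return generate_cohort(GeneratorConfig(n_patients=180, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
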