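import numpy as np
import pytest

from rnflasym.data_model import SECTORS, Cohort, EyeMeasurement, PatientRecord
from rnflasym.simulate import generate_cohort


def make_eye(side, thicknesses, g=None):
    if np.isscalar(thicknesses):
        thicknesses = {s: float(thicknesses) for s in SECTORS}
    return EyeMeasurement(side, dict(thicknesses), g)


def make_patient(pid, right, left, label="healthy", g_right=None, g_left=None):
    return PatientRecord(
        patient_id=pid,
        right=make_eye("right", right, g_right),
        left=make_eye("left", left, g_left),
        label=label,
    )


@pytest.fixture
def toy_cohort():
    """Four patients: two symmetric healthy, two asymmetric glaucoma."""
    return Cohort(
        [
            make_patient("h1", 100.0, 100.0, "healthy"),
            make_patient("h2", 110.0, 108.0, "healthy"),
            make_patient("g1", 120.0, 80.0, "glaucoma"),
            make_patient("g2", 90.0, 130.0, "glaucoma"),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Reference-calibrated synthetic cohort, fixed seed."""
    return generate_cohort(seed=0)
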