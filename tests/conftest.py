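import pytest

from glimscreen.cohort import PatientRecord
from glimscreen.synth import generate_fixture_cohort, reference_cells


def make_record(**overrides) -> PatientRecord:
    """A neutral patient: scores 0 on both instruments, GLIM-negative phenotype."""
    base = dict(
        patient_id="p0",
        age=50,
        sex="male",
        height=1.70,
        weight=60.69,  # BMI 21.0
        ffm=54.91,  # FFMI 19.0
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def total_fixture_cohort():
    return generate_fixture_cohort(reference_cells("gist-total"), seed=7)


@pytest.fixture(scope="session")
def nonsurgical_fixture_cohort():
    return generate_fixture_cohort(reference_cells("gist-nonsurgical"), seed=7)
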