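import numpy as np
import pytest

from voxdose import synthetic_cohort


@pytest.fixture(scope="session")
def cohort_df():
    """Packaged 22-patient cohort table."""
    return synthetic_cohort.load_packaged_cohort()


@pytest.fixture(scope="session")
def male_patient():
    return synthetic_cohort.PatientRecord(
        id="T01", age=60.0, sex="male", weight=80.0, bmi=80.0 / 1.78**2, height=178.0
    )


@pytest.fixture(scope="session")
def female_patient():
    return synthetic_cohort.PatientRecord(
        id="T02", age=45.0, sex="female", weight=60.0, bmi=60.0 / 1.65**2, height=165.0
    )


@pytest.fixture(scope="session")
def male_phantom(male_patient):
    return synthetic_cohort.generate_phantom(male_patient, resolution=48, seed=5)


@pytest.fixture(scope="session")
def female_phantom(female_patient):
    return synthetic_cohort.generate_phantom(female_patient, resolution=48, seed=5)
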