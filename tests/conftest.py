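import numpy as np
import pytest

from reeval import default_profile, generate_cohort, load_coefficient_table
from reeval.cohort import PatientRecord


@pytest.fixture(scope="session")
def registry():
    return load_coefficient_table()


@pytest.fixture(scope="session")
def cohort513():
    """Default synthetic cohort at the published size, fixed seed."""
    return generate_cohort(default_profile(), n=513, seed=1)


@pytest.fixture(scope="session")
def noisefree_lt25():
    """Zero-noise cohort whose REE is exactly the BMI<25 study equation."""
    from dataclasses import replace

    profile = replace(default_profile(), truth_model="new_lt25", noise_sd=1e-12)
    return generate_cohort(profile, n=120, seed=7)


@pytest.fixture
def make_patient():
    def _make(pid="p", sex=1, age=50.0, weight=70.0, height=1.75, ree=1700.0, **kw):
        return PatientRecord(
            patient_id=pid, sex=sex, age=age, weight=weight, height=height,
            ree_measured=ree, **kw,
        )

    return _make


@pytest.fixture
def random_pairs():
    """Random (predicted, measured) pairs for oracle comparisons."""
    rng = np.random.default_rng(42)

    def _make(n):
        measured = rng.uniform(800, 2800, size=n)
        predicted = measured * rng.uniform(0.6, 1.4, size=n)
        return list(zip(predicted, measured))

    return _make
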