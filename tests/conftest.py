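import numpy as np
import pytest

from celsignal.plate_io import ImpedanceTrace, WellCondition
from celsignal.synthetic_data import (
    DEFAULT_COHORT_MIXTURE,
    PatientProfile,
    default_plate_layout,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def cohort_mixture():
    return DEFAULT_COHORT_MIXTURE


@pytest.fixture
def noiseless_profile():
    return PatientProfile(
        "P0001",
        {"cMet": 400.0, "HER1": 100.0, "HER2": 200.0, "HER3_4": 50.0},
        noise_sd=0.0,
    )


@pytest.fixture
def duplicate_layout():
    return default_plate_layout("P0001", n_replicates=2)


def make_trace(well_id, times, values):
    return ImpedanceTrace(well_id, np.asarray(times, float),
                          np.asarray(values, float))


@pytest.fixture
def flat_pair():
    """Treated == control over an inclusive 0..240 minute grid."""
    t = np.arange(241.0)
    base = np.ones_like(t)
    return make_trace("T", t, base), make_trace("C", t, base)


@pytest.fixture
def c_condition():
    return WellCondition("C", "P0001")


@pytest.fixture
def cf3_condition():
    return WellCondition("CF3", "P0001")
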