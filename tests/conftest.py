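"""Shared fixtures. Expensive fits are session-scoped so the suite fits them once."""

import numpy as np
import pytest

from strokeflow.regression import RegressionConfig, fit_pairwise, fit_timeseries
from strokeflow.surface_io import TriangleSurface
from strokeflow.synthetic import PatientParams, generate_patient, make_icosphere

# coarse meshes keep the suite fast; the generator's study conditions (radii,
# times, rates, mismatch) are unchanged
TEST_SUBDIV = 1


@pytest.fixture(scope="session")
def sphere10() -> TriangleSurface:
    return make_icosphere(10.0, 2)


@pytest.fixture(scope="session")
def sphere_small() -> TriangleSurface:
    """20-face icosphere for closed-form / oracle tests."""
    return make_icosphere(10.0, 0)


@pytest.fixture(scope="session")
def patient_noise_free():
    return generate_patient(PatientParams(subdivisions=TEST_SUBDIV, noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def dwi_scenario(patient_noise_free):
    return fit_timeseries(patient_noise_free.dwi_surfaces, RegressionConfig())


@pytest.fixture(scope="session")
def phi_map(patient_noise_free):
    p = patient_noise_free
    return fit_pairwise(p.dwi_surfaces[0], p.mtt_surfaces[0], RegressionConfig())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
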