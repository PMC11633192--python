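import pytest

from n2oiso.datasets import load_isotopocule_survey, survey_measurements
from n2oiso.gas_partition import VesselGeometry
from n2oiso.synthetic_cultures import CultureConfig, simulate_culture


@pytest.fixture(scope="session")
def survey():
    """Bundled strain-mean isotopocule survey (23 rows)."""
    return load_isotopocule_survey()


@pytest.fixture(scope="session")
def survey_records():
    return survey_measurements()


@pytest.fixture(scope="session")
def geometry():
    return VesselGeometry()


@pytest.fixture(scope="session")
def noisefree_culture():
    """Default NO3 culture, measurement noise off (latent == measured)."""
    return simulate_culture(CultureConfig(noise_enabled=False), seed=0)


@pytest.fixture(scope="session")
def noisy_culture():
    return simulate_culture(CultureConfig(), seed=0)
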