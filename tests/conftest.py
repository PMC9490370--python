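import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eemcal.eem_io import WavelengthGrid
from eemcal.synthetic_data import default_design, default_spike_plan, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Default two-analyte design, no noise, no scatter: exactly trilinear."""
    return generate_dataset(default_design(seed=7, noise_sd=0.0, with_scatter=False))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default design with 1% noise and scatter ridges plus 6 spiked pairs."""
    design = default_design(seed=11, noise_sd=0.01, with_scatter=True)
    return generate_dataset(design, spike_plan=default_spike_plan(design))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
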