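import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import venomprint as vp
from venomprint.config import RunConfig, StandardsConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def run_config():
    """Pipeline config pinned to the simulator's true time scale."""
    return dataclasses.replace(
        RunConfig(),
        standards=StandardsConfig(reference_lower_s=15.0, reference_upper_s=45.0),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy two-group dataset shared by pipeline-level tests."""
    cfg = vp.two_group_preset(seed=5, n_individuals=(10, 6))
    return vp.simulate_dataset(cfg)


def make_gaussian_trace(
    apexes, heights, start=0.0, stop=60.0, step=0.02, width=0.08, sample_id="t"
):
    """Synthetic trace of Gaussian peaks on a flat baseline."""
    t = np.arange(start, stop, step)
    f = np.zeros_like(t)
    for apex, h in zip(apexes, heights):
        f += h * np.exp(-0.5 * ((t - apex) / width) ** 2)
    return vp.Trace(sample_id=sample_id, times=t, fluorescence=f)
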