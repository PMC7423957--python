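import numpy as np
import pytest

from mvne.synthgen import SynthSpec, ViewSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset():
    """Three small complete views with clear 3-cluster structure."""
    spec = SynthSpec(
        n_samples=60, n_clusters=3,
        views=[ViewSpec(d=15, center_separation=6.0, noise_sd=1.0),
               ViewSpec(d=10, center_separation=6.0, noise_sd=1.0),
               ViewSpec(d=15, center_separation=6.0, noise_sd=1.0)],
        seed=7)
    return generate(spec)


@pytest.fixture
def incomplete_dataset():
    """Two views with 25% missingness each (every sample kept somewhere)."""
    spec = SynthSpec(
        n_samples=40, n_clusters=3,
        views=[ViewSpec(d=12, missing_fraction=0.25),
               ViewSpec(d=9, missing_fraction=0.25)],
        seed=11)
    return generate(spec)
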