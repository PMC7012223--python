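import numpy as np
import pytest

from pulsescreen import PulseModelParams, build_labeled_dataset


@pytest.fixture(scope="session")
def small_clean_params():
    """20 segments (600 s at 250 Hz) of clean signal — quick to generate."""
    return PulseModelParams(duration=600.0, seed=7)


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """100 segments with 3 spike and 2 poor-contact segments injected."""
    params = PulseModelParams(duration=3000.0, seed=11)
    return build_labeled_dataset(
        params, spike_minutes=1.5, poor_contact_minutes=1.0, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
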