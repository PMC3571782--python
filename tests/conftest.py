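import numpy as np
import pytest

from enosekit.sim import BUILTIN_SPECS, ClassSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_spec():
    """A noiseless, driftless class for closed-form checks."""
    base = BUILTIN_SPECS["fresh_fish"]
    return ClassSpec(label="quiet", amplitude=base.amplitude,
                     rise_time=base.rise_time, baseline=base.baseline,
                     saturation=base.saturation, drift=0.0, noise_sd=0.0)


@pytest.fixture
def two_class_specs():
    """Two well-separated built-in classes (amplitude gaps >> noise sd)."""
    return [BUILTIN_SPECS["fresh_fish"], BUILTIN_SPECS["decayed_fish_day2"]]
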