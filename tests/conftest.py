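import numpy as np
import pytest

from metaceeg.preprocess import bandpass_fir, maxabs_scale
from metaceeg.synthdata import ClassSpec, SynthConfig, generate_oddball


@pytest.fixture(scope="session")
def oddball_small():
    """Two-class single-channel oddball set: 50 non-target + 50 target."""
    cfg = SynthConfig(n_channels=1, class_spec=(
        ClassSpec(label=0, n_epochs=50, erp_amplitude=0.0),
        ClassSpec(label=1, n_epochs=50, erp_amplitude=5.0)), seed=7)
    return generate_oddball(cfg)


@pytest.fixture(scope="session")
def oddball_scaled(oddball_small):
    """Band-limited and MaxAbs-scaled copy, ready for GAN training."""
    return maxabs_scale(bandpass_fir(oddball_small))


@pytest.fixture(scope="session")
def oddball_5ch():
    cfg = SynthConfig(n_channels=5, class_spec=(
        ClassSpec(label=0, n_epochs=30, erp_amplitude=0.0),
        ClassSpec(label=1, n_epochs=30, erp_amplitude=5.0)), seed=11)
    return generate_oddball(cfg)
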