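import numpy as np
import pytest

from fnirsfilt import (
    AMPLITUDE_PRESETS,
    HRFSpec,
    NoiseSpec,
    ProtocolSpec,
    build_boxcar,
    sample_hrf,
)

FS = 5.0


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def hrf():
    return HRFSpec()


@pytest.fixture(scope="session")
def boxcar(protocol):
    return build_boxcar(protocol, FS)


@pytest.fixture(scope="session")
def hrf_kernel(hrf):
    return sample_hrf(hrf, FS)


@pytest.fixture(scope="session")
def amplitude1():
    return AMPLITUDE_PRESETS[0]


@pytest.fixture(scope="session")
def quiet_noise():
    """A noise spec with every stochastic term switched off."""
    comps = tuple((c, 0.0, 0.0, 0.0) for c, *_ in NoiseSpec().components)
    return NoiseSpec(
        components=comps,
        settle_amp=0.0,
        settle_amp_sd=0.0,
        drift_amp=0.0,
        white_sd=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210405)
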