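import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirscpm.optics import HemoSeries

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def band_limited(rng, n_channels, n_samples, fs=10.0, band=(0.01, 0.08)):
    """Independent band-limited channel signals (helper for filter tests).

    Over-generates and crops so the result looks like steady-state data,
    free of filter edge transients.
    """
    from scipy import signal as sps

    pad = 300
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(
        sos, rng.standard_normal((n_channels, n_samples + 2 * pad)), axis=1
    )[:, pad:-pad]
    return x / x.std(axis=1, keepdims=True)


@pytest.fixture
def hemo_series(rng) -> HemoSeries:
    """Eight channels of clean band-limited hemodynamics, 200 s at 10 Hz."""
    hbo = band_limited(rng, 8, 2000)
    return HemoSeries(participant_id="sub-001", hbo=hbo, hbr=-0.5 * hbo, sampling_rate=10.0)
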