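import numpy as np
import pytest

from dolphinpam.audio_io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_recording(rng):
    """1 s of unit-variance white noise at 192 kHz."""
    return Recording(samples=rng.normal(0.0, 1.0, 192000), sample_rate_hz=192000)


def make_snr_series(values, window_length_s=0.002):
    """Build an SnrSeries directly from a list of per-window dB values."""
    from dolphinpam.snr_preprocess import SnrSeries

    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * window_length_s
    return SnrSeries(
        window_length_s=window_length_s, window_start_times=starts, snr_db=values
    )
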