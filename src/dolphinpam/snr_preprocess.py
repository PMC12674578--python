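"""High-pass pre-filtering and the windowed signal-to-noise-ratio series.

Pulsed dolphin vocalizations sit well above the low-frequency pool and
machinery noise, so the signal is first high-pass filtered (Butterworth,
5th order, 3 kHz cut-off by default).  The SNR of each short analysis
window (2 ms by default) is then the variance ratio

    SNR_dB = 10 * log10( var(window) / var(noise segment) )

where the noise segment is a stretch of the filtered recording judged free
of vocalizations — supplied explicitly, or auto-selected as the
minimum-variance 1-second stretch.

The filter is applied forward-backward (zero phase) so that peak times, which
feed inter-click-interval classification downstream, are not biased by phase
delay.  The designed single-pass prototype keeps the textbook Butterworth
property |H(f_c)| = -3 dB; the zero-phase application doubles attenuation
in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from dolphinpam.audio_io import Recording

__all__ = [
    "NoiseProfile",
    "SnrSeries",
    "butter_highpass_sos",
    "highpass_magnitude_db",
    "highpass_filter",
    "estimate_noise_variance",
    "auto_noise_segment",
    "compute_snr_series",
    "SNR_FLOOR_DB",
]

#: Floor substituted for -inf when a window has zero variance, so that
#: downstream arithmetic (sensitivity curves, grouping) stays total.
SNR_FLOOR_DB = -120.0


@dataclass(frozen=True)
class NoiseProfile:
    """Noise reference: sample variance of a vocalization-free segment."""

    variance: float
    segment_start_s: float
    segment_end_s: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"noise variance must be positive, got {self.variance}")


@dataclass
class SnrSeries:
    """Per-window mean SNR (dB) over non-overlapping contiguous windows.

    Windows start at sample 0; a trailing partial window is dropped, so
    ``len(snr_db) == floor(duration / window_length)``.
    """

    window_length_s: float
    window_start_times: np.ndarray
    snr_db: np.ndarray

    @property
    def window_centers(self) -> np.ndarray:
        return self.window_start_times + self.window_length_s / 2.0

    def __len__(self) -> int:
        return self.snr_db.size


def butter_highpass_sos(order: int, cutoff_hz: float, fs: float) -> np.ndarray:
    """Design the single-pass Butterworth high-pass prototype (SOS form)."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={fs / 2}) Hz")
    return signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")


def highpass_magnitude_db(
    freqs_hz: np.ndarray, order: int = 5, cutoff_hz: float = 3000.0, fs: float = 192000.0
) -> np.ndarray:
    """Magnitude response (dB) of the single-pass prototype at ``freqs_hz``."""
    sos = butter_highpass_sos(order, cutoff_hz, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs_hz, float)), fs=fs)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def highpass_filter(rec: Recording, order: int = 5, cutoff_hz: float = 3000.0) -> Recording:
    """Zero-phase Butterworth high-pass filter of a recording."""
    sos = butter_highpass_sos(order, cutoff_hz, rec.sample_rate_hz)
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return Recording(
        samples=filtered, sample_rate_hz=rec.sample_rate_hz, start_time=rec.start_time
    )


def estimate_noise_variance(
    rec: Recording, segment: tuple[float, float], *, min_length_s: float = 0.002
) -> NoiseProfile:
    """Sample variance of a vocalization-free segment of a filtered recording.

    The segment is chosen by the analyst (visual inspection in practice) or
    by :func:`auto_noise_segment`.  It must span at least one analysis
    window and have nonzero variance.
    """
    start_s, end_s = segment
    if not (0.0 <= start_s < end_s <= rec.duration_s + 1e-12):
        raise ValueError(f"noise segment [{start_s}, {end_s}) outside recording")
    if end_s - start_s < min_length_s:
        raise ValueError(
            f"noise segment of {end_s - start_s:.6f} s shorter than one "
            f"{min_length_s:.3f} s analysis window"
        )
    i0 = int(round(start_s * rec.sample_rate_hz))
    i1 = int(round(end_s * rec.sample_rate_hz))
    var = float(np.var(rec.samples[i0:i1], ddof=1))
    if var <= 0.0:
        raise ValueError("noise segment has zero variance (constant signal)")
    return NoiseProfile(variance=var, segment_start_s=start_s, segment_end_s=end_s)


def auto_noise_segment(rec: Recording, length_s: float = 1.0) -> tuple[float, float]:
    """Minimum-variance stretch of ``length_s`` seconds, on a half-length grid.

    A stand-in for the analyst's visual choice of a vocalization-free
    segment: the candidate with the smallest variance is the least likely to
    contain transients.
    """
    n = int(round(length_s * rec.sample_rate_hz))
    if n >= rec.n_samples:
        return (0.0, rec.duration_s)
    hop = max(1, n // 2)
    starts = np.arange(0, rec.n_samples - n + 1, hop)
    variances = [np.var(rec.samples[s : s + n]) for s in starts]
    best = int(starts[int(np.argmin(variances))])
    return (best / rec.sample_rate_hz, (best + n) / rec.sample_rate_hz)


def compute_snr_series(
    rec: Recording, noise: NoiseProfile, window_length_s: float = 0.002
) -> SnrSeries:
    """Windowed variance-ratio SNR series of a filtered recording.

    Each non-overlapping ``window_length_s`` window (starting at sample 0,
    trailing remainder dropped) gets
    ``10*log10(var(window)/noise.variance)``; zero-variance windows are
    floored at :data:`SNR_FLOOR_DB`.
    """
    if window_length_s <= 0:
        raise ValueError("window_length_s must be positive")
    win = int(round(window_length_s * rec.sample_rate_hz))
    if win < 2:
        raise ValueError(f"window of {window_length_s} s spans {win} sample(s); need >= 2")
    n_win = rec.n_samples // win
    if n_win == 0:
        raise ValueError("recording shorter than one analysis window")
    frames = rec.samples[: n_win * win].reshape(n_win, win)
    variances = frames.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(variances / noise.variance)
    snr = np.maximum(snr, SNR_FLOOR_DB)
    starts = np.arange(n_win) * (win / rec.sample_rate_hz)
    return SnrSeries(
        window_length_s=win / rec.sample_rate_hz, window_start_times=starts, snr_db=snr
    )
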