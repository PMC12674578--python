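"""WAV input/output and the block-file naming convention.

Autonomous underwater recorders of the kind used in pool-based PAM studies
store audio as consecutive 5-minute mono PCM WAV blocks whose file names
encode the wall-clock start of the block, ``YYYYMMDD_hhmmss_<kHz>.wav``
(e.g. ``20211120_102100_192.wav`` for a block starting 2021-11-20 10:21:00
sampled at 192 kHz).  This module reads and writes such files, parses and
formats the naming convention, and extracts clips.

Amplitude convention: samples are held as float64 in the symmetric range
[-1, 1] (int16 payloads divided by 32768).  Min-max normalization to [0, 1]
exists only as an *export* option for released whistle clips; analysis code
always works on the symmetric representation because a [0, 1] rescale adds a
DC offset that corrupts variance-based SNR.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Recording",
    "read_wav",
    "write_wav",
    "parse_block_timestamp",
    "format_block_name",
    "clip_name",
    "extract_clip",
]

_BLOCK_RE = re.compile(r"^(\d{8})_(\d{6})_(\d+)(?:\.wav)?$")

#: Full scale of a 16-bit PCM sample; int16 payloads map to [-1, 1).
PCM16_FULL_SCALE = 32768.0


@dataclass
class Recording:
    """A single-channel amplitude series with its sample rate.

    Parameters
    ----------
    samples
        Dimensionless amplitudes, float64, all finite.
    sample_rate_hz
        Sampling rate in Hz, positive.
    start_time
        Absolute wall-clock start of the recording, or ``None`` when the
        recording is not anchored to a block file.
    """

    samples: np.ndarray
    sample_rate_hz: int
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {self.samples.shape}")
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


def read_wav(path: str | Path, *, channel: int | None = None) -> Recording:
    """Read a PCM or float WAV file into a :class:`Recording`.

    Integer payloads are scaled to [-1, 1) by the type's full scale
    (32768 for int16); float payloads are taken as-is.  Multi-channel files
    are rejected unless ``channel`` selects one — the study devices are mono.
    The block start time is parsed from the file name when it follows the
    block naming convention, else left ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path.name}: {data.shape[1]}-channel WAV; pass channel= to select one"
            )
        data = data[:, channel]
    if data.size == 0:
        raise ValueError(f"{path.name}: zero-length WAV")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / PCM16_FULL_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path.name}: unsupported WAV sample type {data.dtype}")
    start = None
    try:
        start = parse_block_timestamp(path.name)
    except ValueError:
        pass
    return Recording(samples=samples, sample_rate_hz=int(rate), start_time=start)


def write_wav(path: str | Path, rec: Recording, *, subtype: str = "pcm16") -> None:
    """Write a :class:`Recording` as WAV (``pcm16`` or ``float32``).

    For pcm16, samples are clipped to [-1, 1] and quantized at full scale.
    """
    path = Path(path)
    if subtype == "pcm16":
        clipped = np.clip(rec.samples, -1.0, 32767.0 / PCM16_FULL_SCALE)
        payload = np.round(clipped * PCM16_FULL_SCALE).astype(np.int16)
    elif subtype == "float32":
        payload = rec.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    wavfile.write(str(path), rec.sample_rate_hz, payload)


def parse_block_timestamp(filename: str) -> datetime:
    """Parse the wall-clock block start from ``YYYYMMDD_hhmmss_<kHz>.wav``.

    >>> parse_block_timestamp("20211120_102100_192.wav")
    datetime.datetime(2021, 11, 20, 10, 21)
    """
    m = _BLOCK_RE.match(Path(filename).name)
    if m is None:
        raise ValueError(f"{filename!r} does not match YYYYMMDD_hhmmss_<kHz>.wav")
    try:
        return datetime.strptime(m.group(1) + m.group(2), "%Y%m%d%H%M%S")
    except ValueError as exc:
        raise ValueError(f"{filename!r}: invalid date/time fields") from exc


def format_block_name(start: datetime, rate_khz: int = 192) -> str:
    """Inverse of :func:`parse_block_timestamp` (1-second resolution)."""
    return f"{start:%Y%m%d_%H%M%S}_{rate_khz}.wav"


def clip_name(block_base: str, offset_s: float, tag: str = "W", ext: str = "wav") -> str:
    """Released-dataset clip naming: ``<base>-colspectro-<tag>-<OFFSET>.<ext>``.

    OFFSET is the integer second (floor) from the block start.
    """
    base = block_base[:-4] if block_base.endswith(".wav") else block_base
    return f"{base}-colspectro-{tag}-{int(np.floor(offset_s))}.{ext}"


def extract_clip(
    rec: Recording, start_s: float, end_s: float, normalize: bool = False
) -> Recording:
    """Extract ``[start_s, end_s)`` as a new recording.

    With ``normalize=True`` the clip is min-max scaled to [0, 1], the export
    convention of released whistle clips.  Analysis code must keep
    ``normalize=False``: the rescaled clip has a DC offset and altered
    variance.  A zero-variance clip cannot be normalized; it is returned as
    all zeros with a warning.
    """
    if not (0.0 <= start_s < end_s <= rec.duration_s + 1e-12):
        raise ValueError(
            f"clip span [{start_s}, {end_s}) outside recording of {rec.duration_s:.6f} s"
        )
    i0 = int(round(start_s * rec.sample_rate_hz))
    i1 = int(round(end_s * rec.sample_rate_hz))
    out = rec.samples[i0:i1].copy()
    if normalize:
        lo, hi = out.min(), out.max()
        if hi - lo <= 0.0:
            warnings.warn("zero-variance clip: returning constant 0", stacklevel=2)
            out = np.zeros_like(out)
        else:
            out = (out - lo) / (hi - lo)
    start_time = None
    if rec.start_time is not None:
        from datetime import timedelta

        start_time = rec.start_time + timedelta(seconds=start_s)
    return Recording(samples=out, sample_rate_hz=rec.sample_rate_hz, start_time=start_time)
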