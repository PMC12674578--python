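"""Whistle-annotation management: label I/O, duration classes, clip export.

Whistles (tonal FM vocalizations, roughly 1-25 kHz, 0.1 s to a few seconds)
are detected by a human analyst on spectrograms; this module handles what
surrounds that manual step.  Annotations travel as Audacity-importable
tab-separated label files (start s, end s, tag), whistles are binned into
four duration classes with boundaries at 0.2, 0.4 and 0.8 s, and each
annotation can be exported as a min-max-normalized WAV clip plus a 0-25 kHz
linear-scale spectrogram PNG following the released-dataset naming
convention ``<block>-colspectro-W-<OFFSET>.{wav,png}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dolphinpam.audio_io import Recording, clip_name, extract_clip, write_wav

__all__ = [
    "CLASS_BOUNDS_S",
    "WhistleAnnotation",
    "assign_duration_class",
    "read_labels",
    "write_labels",
    "export_whistle_assets",
    "count_concurrent",
]

#: Duration-class boundaries in seconds: class 1 <= 0.2 < class 2 < 0.4
#: <= class 3 < 0.8 <= class 4.
CLASS_BOUNDS_S = (0.2, 0.4, 0.8)


@dataclass(frozen=True)
class WhistleAnnotation:
    """One whistle: start/end in seconds from block start, with a tag."""

    start_s: float
    end_s: float
    tag: str = "W"
    source_block: str | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"end ({self.end_s}) must exceed start ({self.start_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def duration_class(self) -> int:
        return assign_duration_class(self.duration_s)


def assign_duration_class(duration_s: float) -> int:
    """Whistle duration class 1-4.

    Class 1: d <= 0.2 s; class 2: 0.2 < d < 0.4 s; class 3: 0.4 <= d <
    0.8 s; class 4: d >= 0.8 s.  The published rule leaves d = 0.4 s
    unassigned (class 2 open above, class 3 open below); it goes to class 3
    here so every boundary except the stated closures at 0.2 and 0.8 is
    upper-open.
    """
    if not duration_s > 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    if duration_s <= CLASS_BOUNDS_S[0]:
        return 1
    if duration_s < CLASS_BOUNDS_S[1]:
        return 2
    if duration_s < CLASS_BOUNDS_S[2]:
        return 3
    return 4


def read_labels(path: str | Path, *, source_block: str | None = None) -> list[WhistleAnnotation]:
    """Read a tab-separated label file (start s, end s, tag).

    Malformed rows raise with their 1-based line number.  Blank lines are
    ignored; an empty file yields an empty list.
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            try:
                start_s, end_s = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric start/end") from exc
            if end_s <= start_s:
                raise ValueError(f"{path}:{lineno}: end {end_s} <= start {start_s}")
            annotations.append(
                WhistleAnnotation(start_s=start_s, end_s=end_s, tag=parts[2], source_block=source_block)
            )
    return annotations


def write_labels(annotations: list[WhistleAnnotation], path: str | Path) -> None:
    """Write annotations as a tab-separated label file, sorted by start.

    Times are printed at 6 decimals (microsecond precision), so
    write -> read round-trips values stored at that precision.
    """
    with open(path, "w") as fh:
        for ann in sorted(annotations, key=lambda a: a.start_s):
            fh.write(f"{ann.start_s:.6f}\t{ann.end_s:.6f}\t{ann.tag}\n")


def export_whistle_assets(
    rec: Recording,
    ann: WhistleAnnotation,
    out_dir: str | Path,
    *,
    block_base: str | None = None,
    nfft: int = 1024,
    max_freq_hz: float = 25000.0,
    cmap: str = "viridis",
) -> tuple[Path, Path]:
    """Export one annotation as normalized WAV clip + spectrogram PNG.

    The clip is min-max normalized to [0, 1] (released-dataset convention)
    and written as float32 WAV.  The spectrogram uses a Hann window of
    ``nfft`` points with 50% overlap, shown 0-25 kHz on a linear frequency
    axis.  File names follow ``<base>-colspectro-W-<OFFSET>``, OFFSET the
    integer second of the whistle start within the block.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import signal as sps

    if ann.end_s > rec.duration_s:
        raise ValueError(f"annotation [{ann.start_s}, {ann.end_s}) outside recording")
    if block_base is None:
        block_base = ann.source_block or (
            rec.start_time.strftime("%Y%m%d_%H%M%S") + f"_{rec.sample_rate_hz // 1000}"
            if rec.start_time is not None
            else "block"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clip = extract_clip(rec, ann.start_s, ann.end_s, normalize=True)
    wav_path = out_dir / clip_name(block_base, ann.start_s, tag=ann.tag, ext="wav")
    write_wav(wav_path, clip, subtype="float32")

    raw = extract_clip(rec, ann.start_s, ann.end_s, normalize=False)
    nperseg = min(nfft, raw.n_samples)
    freqs, times, sxx = sps.spectrogram(
        raw.samples,
        fs=rec.sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=nfft,
    )
    keep = freqs <= max_freq_hz
    fig, ax = plt.subplots(figsize=(6, 4))
    with np.errstate(divide="ignore"):
        ax.pcolormesh(
            times, freqs[keep] / 1000.0, 10.0 * np.log10(np.maximum(sxx[keep], 1e-30)),
            shading="auto", cmap=cmap,
        )
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Frequency (kHz)")
    ax.set_ylim(0, max_freq_hz / 1000.0)
    png_path = out_dir / clip_name(block_base, ann.start_s, tag=ann.tag, ext="png")
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return wav_path, png_path


def count_concurrent(annotations: list[WhistleAnnotation]) -> int:
    """Maximum number of annotations overlapping at any instant.

    Boundary sweep over starts (+1) and ends (-1); an annotation ending
    exactly where another starts does not overlap it.
    """
    if not annotations:
        return 0
    events = []
    for ann in annotations:
        events.append((ann.start_s, 1))
        events.append((ann.end_s, -1))
    events.sort(key=lambda e: (e[0], e[1]))  # ends before starts at ties
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best
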