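"""Detection of isolated SNR peaks and ICI-based classification of sequences.

A 2-ms analysis window holds a *peak* when its mean SNR reaches the
detection threshold Th while both neighboring windows stay below Th — the
pulse is an isolated transient, not a plateau.  Detected peaks are grouped
into sequences (a gap above ``max_gap_s`` starts a new sequence; sequences
shorter than ``min_peaks`` are discarded) and each sequence is classified by
its mean inter-click interval (ICI):

* feeding buzz (FB):            mean ICI <= 0.017 s
* burst-pulse sound (BPS):      0.017 s < mean ICI <= 0.22 s
* echolocation click train (ECT): mean ICI > 0.22 s

Th is either supplied or chosen from a sensitivity analysis of the peak
count versus threshold (the knee of the count curve).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dolphinpam.audio_io import Recording
from dolphinpam.snr_preprocess import (
    SnrSeries,
    auto_noise_segment,
    compute_snr_series,
    estimate_noise_variance,
    highpass_filter,
)

__all__ = [
    "FB_MAX_ICI_S",
    "BPS_MAX_ICI_S",
    "PeakEvent",
    "PulseSequence",
    "SensitivityCurve",
    "detect_peaks",
    "threshold_sensitivity",
    "group_peaks",
    "classify_mean_ici",
    "detect_and_classify",
    "write_sequence_labels",
    "write_sequence_csv",
]

#: Mean-ICI upper bound (inclusive) for a feeding buzz, seconds.
FB_MAX_ICI_S = 0.017
#: Mean-ICI upper bound (inclusive) for a burst-pulse sound, seconds.
BPS_MAX_ICI_S = 0.22


@dataclass(frozen=True)
class PeakEvent:
    """An isolated supra-threshold SNR window (time at window center)."""

    time_s: float
    snr_db: float


@dataclass
class PulseSequence:
    """A group of peak times with per-sequence ICI statistics and category."""

    peak_times_s: np.ndarray
    peak_snrs_db: np.ndarray
    category: str = field(init=False)

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        self.peak_snrs_db = np.asarray(self.peak_snrs_db, dtype=float)
        if self.peak_times_s.size < 2:
            raise ValueError("a pulse sequence needs at least 2 peaks (1 ICI)")
        if np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        self.category = classify_mean_ici(self.mean_ici_s)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times_s.size)

    @property
    def icis_s(self) -> np.ndarray:
        return np.diff(self.peak_times_s)

    @property
    def mean_ici_s(self) -> float:
        return float(self.icis_s.mean())

    @property
    def start_s(self) -> float:
        return float(self.peak_times_s[0])

    @property
    def end_s(self) -> float:
        return float(self.peak_times_s[-1])

    @property
    def duration_s(self) -> float:
        """Last minus first peak time."""
        return self.end_s - self.start_s

    @property
    def mean_snr_db(self) -> float:
        """Mean SNR over the sequence's peak windows."""
        return float(self.peak_snrs_db.mean())


@dataclass
class SensitivityCurve:
    """Peak counts versus detection threshold.

    ``n_above`` counts windows meeting the threshold alone (criterion 1) and
    is non-increasing in the threshold; ``n_peaks`` applies the full
    isolated-peak rule and may be locally non-monotone (raising Th can
    isolate a window whose neighbor drops below Th).  The suggested
    operating threshold is the knee of the ``n_above`` curve — the grid
    point maximizing the discrete second difference, where the steep
    noise-driven decay gives way to the plateau of genuine transients.
    """

    thresholds_db: np.ndarray
    n_peaks: np.ndarray
    n_above: np.ndarray

    @property
    def suggested_th_db(self) -> float:
        c = self.n_above.astype(float)
        if c.size < 3:
            return float(self.thresholds_db[-1])
        # curvature on log counts: the exponential noise decay is near-linear
        # there, so the largest positive second difference marks the bend
        # toward the signal plateau; thresholds whose plateau is already
        # empty are not candidates
        lc = np.log10(c + 1.0)
        d2 = lc[2:] - 2.0 * lc[1:-1] + lc[:-2]
        valid = np.flatnonzero(c[2:] > 0)
        if valid.size == 0:
            return float(self.thresholds_db[-1])
        idx = 1 + valid[int(np.argmax(d2[valid]))]
        # the knee can land inside a steep noise decay when that decay spans
        # few grid points; advance until the count is locally flat (< 20%
        # drop per step) or exhausted, which is the actual plateau onset
        while idx + 1 < c.size and c[idx] > 0 and (c[idx] - c[idx + 1]) > 0.2 * c[idx]:
            idx += 1
        return float(self.thresholds_db[idx])


def detect_peaks(series: SnrSeries, th_db: float, *, mode: str = "isolated") -> list[PeakEvent]:
    """Find isolated supra-threshold windows.

    ``mode="isolated"`` (default) is the two-sided rule: window *i* is a
    peak iff ``snr[i] >= th`` and both neighbors are ``< th``; adjacent
    supra-threshold windows therefore yield no peak, and the first/last
    windows never qualify.  ``mode="local_max"`` relaxes this to a strict
    local maximum above Th (``snr[i] >= th``, ``snr[i] > snr[i-1]``,
    ``snr[i] >= snr[i+1]``) for dense buzzes whose clicks land in adjacent
    windows.
    """
    snr = series.snr_db
    if snr.size == 0:
        raise ValueError("empty SNR series")
    if snr.size < 3:
        return []
    mid, prev, nxt = snr[1:-1], snr[:-2], snr[2:]
    if mode == "isolated":
        hits = (mid >= th_db) & (prev < th_db) & (nxt < th_db)
    elif mode == "local_max":
        hits = (mid >= th_db) & (mid > prev) & (mid >= nxt)
    else:
        raise ValueError(f"unknown peak mode {mode!r}")
    centers = series.window_centers
    return [
        PeakEvent(time_s=float(centers[i + 1]), snr_db=float(mid[i]))
        for i in np.flatnonzero(hits)
    ]


def threshold_sensitivity(
    series: SnrSeries, th_grid: np.ndarray, *, mode: str = "isolated"
) -> SensitivityCurve:
    """Sweep the detection threshold over ``th_grid`` and count peaks."""
    th_grid = np.asarray(th_grid, dtype=float)
    if th_grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any(np.diff(th_grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    n_peaks = np.array([len(detect_peaks(series, th, mode=mode)) for th in th_grid])
    n_above = np.array([int(np.sum(series.snr_db >= th)) for th in th_grid])
    return SensitivityCurve(thresholds_db=th_grid, n_peaks=n_peaks, n_above=n_above)


def group_peaks(
    peaks: list[PeakEvent], max_gap_s: float = 2.0, min_peaks: int = 3
) -> list[PulseSequence]:
    """Partition time-sorted peaks into sequences.

    A new sequence starts when the gap to the previous peak exceeds
    ``max_gap_s`` (2 s default, comfortably above the ECT ICI regime);
    sequences with fewer than ``min_peaks`` peaks (3 default, so the mean
    ICI averages >= 2 intervals) are discarded.
    """
    if not peaks:
        return []
    times = np.array([p.time_s for p in peaks])
    if np.any(np.diff(times) < 0):
        raise ValueError("peaks must be time-sorted")
    breaks = np.flatnonzero(np.diff(times) > max_gap_s) + 1
    sequences = []
    for chunk in np.split(np.arange(times.size), breaks):
        if chunk.size < max(min_peaks, 2):
            continue
        sequences.append(
            PulseSequence(
                peak_times_s=times[chunk],
                peak_snrs_db=np.array([peaks[i].snr_db for i in chunk]),
            )
        )
    return sequences


def classify_mean_ici(mean_ici_s: float) -> str:
    """Map a mean inter-click interval to FB / BPS / ECT.

    The partition is total and exclusive on mean ICI > 0: FB up to and
    including 0.017 s, BPS up to and including 0.22 s, ECT above.
    """
    if not mean_ici_s > 0:
        raise ValueError(f"mean ICI must be positive, got {mean_ici_s}")
    if mean_ici_s <= FB_MAX_ICI_S:
        return "FB"
    if mean_ici_s <= BPS_MAX_ICI_S:
        return "BPS"
    return "ECT"


def detect_and_classify(
    rec: Recording,
    th_db: float | None = None,
    *,
    filter_order: int = 5,
    cutoff_hz: float = 3000.0,
    window_length_s: float = 0.002,
    noise_segment: tuple[float, float] | None = None,
    max_gap_s: float = 2.0,
    min_peaks: int = 3,
    peak_mode: str = "isolated",
    th_grid_db: np.ndarray | None = None,
) -> list[PulseSequence]:
    """Full pulsed-vocalization pipeline on one recording.

    Filter -> noise reference (explicit segment or minimum-variance auto
    selection) -> windowed SNR -> peak detection at ``th_db`` (or at the
    sensitivity-curve knee when ``th_db`` is ``None``) -> grouping ->
    ICI classification.
    """
    filtered = highpass_filter(rec, order=filter_order, cutoff_hz=cutoff_hz)
    if noise_segment is None:
        noise_segment = auto_noise_segment(filtered)
    noise = estimate_noise_variance(filtered, noise_segment, min_length_s=window_length_s)
    series = compute_snr_series(filtered, noise, window_length_s=window_length_s)
    if th_db is None:
        if th_grid_db is None:
            th_grid_db = np.arange(0.0, 30.5, 0.5)
        th_db = threshold_sensitivity(series, th_grid_db, mode=peak_mode).suggested_th_db
    peaks = detect_peaks(series, th_db, mode=peak_mode)
    return group_peaks(peaks, max_gap_s=max_gap_s, min_peaks=min_peaks)


def write_sequence_labels(sequences: list[PulseSequence], path: str | Path) -> None:
    """Audacity-importable tab-separated label file (start, end, category)."""
    with open(path, "w") as fh:
        for seq in sorted(sequences, key=lambda s: s.start_s):
            fh.write(f"{seq.start_s:.6f}\t{seq.end_s:.6f}\t{seq.category}\n")


def write_sequence_csv(sequences: list[PulseSequence], path: str | Path) -> None:
    """Per-sequence metrics as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "end_s", "category", "n_peaks", "mean_ici_s", "duration_s", "mean_snr_db"])
        for seq in sorted(sequences, key=lambda s: s.start_s):
            w.writerow(
                [
                    f"{seq.start_s:.6f}",
                    f"{seq.end_s:.6f}",
                    seq.category,
                    seq.n_peaks,
                    f"{seq.mean_ici_s:.6f}",
                    f"{seq.duration_s:.6f}",
                    f"{seq.mean_snr_db:.3f}",
                ]
            )
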