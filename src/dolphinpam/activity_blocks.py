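"""Daily activity schedule, 5-minute block counting, and exclusions.

The study day at the marine park alternates structured sessions — ordinary
training (ORD), a play session (PLAY), and an experimental "fish from the
roof" feeding session (FFR) — with unstructured daytime activity (FREE_ACT)
and an overnight baseline (NIGHT, 19:00 to 07:00 the next morning).
Recordings arrive as 5-minute blocks; each block is labeled with the
activity containing its midpoint, vocalization events are tallied into the
block containing their start time, and two kinds of rows are flagged out of
the statistics: blocks intersecting an exclusion window (05:00-07:00, a
period of uncontrolled external disturbance) and FREE_ACT blocks, whose
behavioral context is unconstrained.

The resulting per-block count table (one row per block: activity label,
whistle count, per-duration-class whistle counts, per-category pulsed
counts, exclusion flag) is the interchange format between detection and
statistics, serialized as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd

__all__ = [
    "ACTIVITY_LABELS",
    "BLOCK_LENGTH_S",
    "ActivityWindow",
    "VocalEvent",
    "build_schedule",
    "default_schedule",
    "default_exclusions",
    "assign_block_activity",
    "block_grid",
    "count_events",
    "apply_exclusions",
    "write_block_table",
    "read_block_table",
]

ACTIVITY_LABELS = ("ORD", "PLAY", "FFR", "NIGHT", "FREE_ACT")
BLOCK_LENGTH_S = 300

PULSED_CATEGORIES = ("ECT", "BPS", "FB")

_TABLE_COLUMNS = [
    "block_start",
    "activity",
    "n_whistles",
    "n_class1",
    "n_class2",
    "n_class3",
    "n_class4",
    "n_ECT",
    "n_BPS",
    "n_FB",
    "excluded",
]


@dataclass(frozen=True)
class ActivityWindow:
    """A labeled half-open time window [start, end)."""

    label: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ValueError(f"unknown activity label {self.label!r}")
        if not self.end > self.start:
            raise ValueError(f"window end {self.end} not after start {self.start}")

    def contains(self, t: datetime) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class VocalEvent:
    """A timed vocalization: a whistle (with duration) or a pulsed category."""

    time: datetime
    kind: str  # "W", "ECT", "BPS" or "FB"
    duration_s: float | None = None  # whistles only


def build_schedule(
    structured: list[ActivityWindow],
    coverage: tuple[datetime, datetime],
) -> list[ActivityWindow]:
    """Fill a coverage span with structured windows plus FREE_ACT gaps.

    ``structured`` holds the ORD/PLAY/FFR sessions and the NIGHT window;
    they must not overlap.  Every gap inside ``coverage`` becomes FREE_ACT,
    so the returned schedule partitions the span.
    """
    start, end = coverage
    if not end > start:
        raise ValueError("coverage end must be after start")
    windows = sorted(structured, key=lambda w: w.start)
    for a, b in zip(windows, windows[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping windows: {a.label} {a.end} / {b.label} {b.start}")
    out: list[ActivityWindow] = []
    cursor = start
    for w in windows:
        if w.end <= start or w.start >= end:
            continue
        w_start, w_end = max(w.start, start), min(w.end, end)
        if w_start > cursor:
            out.append(ActivityWindow("FREE_ACT", cursor, w_start))
        out.append(ActivityWindow(w.label, w_start, w_end))
        cursor = w_end
    if cursor < end:
        out.append(ActivityWindow("FREE_ACT", cursor, end))
    return out


def default_schedule() -> list[ActivityWindow]:
    """The study day's schedule: structured sessions, NIGHT, FREE_ACT gaps.

    Six ORD sessions, one PLAY and one FFR on 2021-11-20/21, NIGHT from
    19:00 to 07:00; coverage matches the recording span (first block starts
    10:21 on day 1, last block starts 10:11 and ends 10:16 on day 2), so
    the block grid coincides with the block-file names.
    """
    d1, d2 = datetime(2021, 11, 20), datetime(2021, 11, 21)

    def at(day: datetime, hhmm: str) -> datetime:
        h, m = hhmm.split(":")
        return day + timedelta(hours=int(h), minutes=int(m))

    rows = [
        ("ORD", d1, "10:20", "11:00"),
        ("ORD", d1, "12:00", "12:45"),
        ("ORD", d1, "14:45", "15:15"),
        ("PLAY", d1, "15:20", "16:00"),
        ("FFR", d1, "16:05", "16:45"),
        ("ORD", d1, "16:50", "17:25"),
        ("ORD", d2, "9:30", "10:00"),
    ]
    structured = [ActivityWindow(lbl, at(day, s), at(day, e)) for lbl, day, s, e in rows]
    structured.append(ActivityWindow("NIGHT", at(d1, "19:00"), at(d2, "7:00")))
    coverage = (at(d1, "10:21"), at(d2, "10:16"))
    return build_schedule(structured, coverage)


def default_exclusions() -> list[tuple[datetime, datetime]]:
    """Disturbance window excluded from statistics: 05:00-07:00 on day 2."""
    d2 = datetime(2021, 11, 21)
    return [(d2 + timedelta(hours=5), d2 + timedelta(hours=7))]


def assign_block_activity(block_start: datetime, schedule: list[ActivityWindow]) -> str:
    """Label of the window containing the block midpoint.

    A block is [start, start + 300 s); the midpoint rule decides blocks
    straddling a session boundary.
    """
    midpoint = block_start + timedelta(seconds=BLOCK_LENGTH_S / 2)
    for w in schedule:
        if w.contains(midpoint):
            return w.label
    raise ValueError(f"schedule does not cover block midpoint {midpoint}")


def block_grid(schedule: list[ActivityWindow]) -> list[datetime]:
    """Consecutive 5-minute block starts covering the schedule span."""
    start = min(w.start for w in schedule)
    end = max(w.end for w in schedule)
    grid = []
    t = start
    while t < end:
        grid.append(t)
        t += timedelta(seconds=BLOCK_LENGTH_S)
    return grid


def count_events(
    events: list[VocalEvent], schedule: list[ActivityWindow]
) -> pd.DataFrame:
    """Tally events into per-block rows over the schedule's block grid.

    Each event falls in the unique half-open block containing its start
    time.  Row order and content are independent of the event order.
    Columns: block_start, activity, n_whistles, n_class1..4, n_ECT, n_BPS,
    n_FB, excluded (False until :func:`apply_exclusions`).
    """
    from dolphinpam.whistle_tools import assign_duration_class

    grid = block_grid(schedule)
    grid_start = grid[0]
    rows = {
        bs: {
            "block_start": bs,
            "activity": assign_block_activity(bs, schedule),
            "n_whistles": 0,
            "n_class1": 0,
            "n_class2": 0,
            "n_class3": 0,
            "n_class4": 0,
            "n_ECT": 0,
            "n_BPS": 0,
            "n_FB": 0,
            "excluded": False,
        }
        for bs in grid
    }
    span_end = grid[-1] + timedelta(seconds=BLOCK_LENGTH_S)
    for ev in events:
        if not (grid_start <= ev.time < span_end):
            raise ValueError(f"event at {ev.time} outside schedule coverage")
        idx = int((ev.time - grid_start).total_seconds() // BLOCK_LENGTH_S)
        row = rows[grid[idx]]
        if ev.kind == "W":
            if ev.duration_s is None:
                raise ValueError("whistle event requires duration_s")
            row["n_whistles"] += 1
            row[f"n_class{assign_duration_class(ev.duration_s)}"] += 1
        elif ev.kind in PULSED_CATEGORIES:
            row[f"n_{ev.kind}"] += 1
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return pd.DataFrame([rows[bs] for bs in grid], columns=_TABLE_COLUMNS)


def apply_exclusions(
    table: pd.DataFrame,
    exclusion_windows: list[tuple[datetime, datetime]] | None = None,
    *,
    flag_free_act: bool = True,
) -> pd.DataFrame:
    """Flag rows to drop from statistics; returns a copy.

    A block is excluded when its half-open span intersects any exclusion
    window, or (by default) when its activity is FREE_ACT — unstructured
    behavior gives no reliable context.  Rows stay in the table; statistics
    readers filter on the flag.
    """
    if exclusion_windows is None:
        exclusion_windows = default_exclusions()
    out = table.copy()
    excluded = out["excluded"].to_numpy(copy=True)
    for i, bs in enumerate(out["block_start"]):
        be = bs + timedelta(seconds=BLOCK_LENGTH_S)
        for (x0, x1) in exclusion_windows:
            if bs < x1 and x0 < be:
                excluded[i] = True
    out["excluded"] = excluded
    if flag_free_act:
        out.loc[out["activity"] == "FREE_ACT", "excluded"] = True
    return out


def write_block_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV export with block_start rendered as YYYYMMDD_hhmmss."""
    out = table.copy()
    out["block_start"] = [bs.strftime("%Y%m%d_%H%M%S") for bs in out["block_start"]]
    out.to_csv(path, index=False)


def read_block_table(path: str | Path) -> pd.DataFrame:
    """Read a block-count CSV back, restoring timestamps and dtypes."""
    df = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["block_start"] = [
        datetime.strptime(str(v), "%Y%m%d_%H%M%S") for v in df["block_start"]
    ]
    df["excluded"] = df["excluded"].astype(bool)
    return df[_TABLE_COLUMNS]
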