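"""Activity-interval logs, analysis windows, and per-activity slicing.

Residents' days are annotated as half-open intervals [start, end) carrying
one of six activities-of-daily-living labels.  Features are aggregated over
two window kinds anchored to each questionnaire:

* ``last_24h`` — the 24 hours ending at the questionnaire answer time;
* ``post_wake_4h`` — the 4 hours following a wake event, where waking is the
  end of the last sleeping interval finishing between 00:00 and 14:00 local.

All timestamps are timezone-naive local time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The six daily-living activity labels of the study protocol.
ACTIVITIES = ("bathing", "cooking", "eating", "going_out", "sleeping", "other")

WINDOW_LENGTHS = {"last_24h": pd.Timedelta(hours=24), "post_wake_4h": pd.Timedelta(hours=4)}

#: Wake events are sleeping intervals ending within this local-time span.
WAKE_SEARCH_START = pd.Timedelta(hours=0)
WAKE_SEARCH_END = pd.Timedelta(hours=14)


@dataclass(frozen=True)
class AnalysisWindow:
    """A half-open aggregation span [start, end) of fixed length."""

    kind: str
    anchor: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp


def load_activity_log(path, activity_set=ACTIVITIES) -> pd.DataFrame:
    """Read and validate an activity-interval CSV.

    The file has columns ``subject_id,start,end,label``.  Intervals are
    returned sorted by (subject, start); unknown labels and within-subject
    overlaps are rejected.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    return validate_intervals(df, activity_set=activity_set)


def validate_intervals(df: pd.DataFrame, activity_set=ACTIVITIES) -> pd.DataFrame:
    """Validate an in-memory interval frame (see :func:`load_activity_log`)."""
    required = {"subject_id", "start", "end", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"activity log missing columns {sorted(missing)}")
    out = df.copy()
    out["start"] = pd.to_datetime(out["start"])
    out["end"] = pd.to_datetime(out["end"])
    unknown = sorted(set(out["label"]) - set(activity_set))
    if unknown:
        raise ValidationError(f"unknown activity labels {unknown}")
    if (out["start"] >= out["end"]).any():
        bad = out.index[out["start"] >= out["end"]].tolist()
        raise ValidationError(f"intervals with start >= end at rows {bad}")
    out = out.sort_values(["subject_id", "start"], kind="stable").reset_index(drop=True)
    for _, grp in out.groupby("subject_id", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = np.flatnonzero(starts[1:] < ends[:-1])
        if overlap.size:
            i = int(overlap[0])
            a, b = grp.index[i], grp.index[i + 1]
            raise ValidationError(f"overlapping intervals at rows {a} and {b}")
    return out


def wake_time(intervals: pd.DataFrame, date) -> pd.Timestamp | None:
    """End of the last sleeping interval ending on `date` before 14:00.

    Returns ``None`` when the morning has no qualifying sleep end (the
    day's post-wake features then become missing).
    """
    day = pd.Timestamp(date).normalize()
    lo, hi = day + WAKE_SEARCH_START, day + WAKE_SEARCH_END
    sleep = intervals[intervals["label"] == "sleeping"]
    ends = sleep["end"]
    qualifying = ends[(ends >= lo) & (ends < hi)]
    if qualifying.empty:
        return None
    return qualifying.max()


def make_window(kind: str, anchor) -> AnalysisWindow:
    """Build an analysis window from its anchor.

    ``last_24h`` spans [anchor - 24 h, anchor); ``post_wake_4h`` spans
    [anchor, anchor + 4 h) with the wake time as anchor.
    """
    if kind not in WINDOW_LENGTHS:
        raise ValidationError(f"unknown window kind {kind!r}")
    anchor = pd.Timestamp(anchor)
    length = WINDOW_LENGTHS[kind]
    if kind == "last_24h":
        return AnalysisWindow(kind, anchor, anchor - length, anchor)
    return AnalysisWindow(kind, anchor, anchor, anchor + length)


def clip_to_window(intervals: pd.DataFrame, window: AnalysisWindow) -> pd.DataFrame:
    """Intersect intervals with [window.start, window.end).

    Partially overlapping intervals are truncated; empty intersections are
    dropped.  Idempotent under re-clipping to the same window.
    """
    start = intervals["start"].clip(lower=window.start)
    end = intervals["end"].clip(upper=window.end)
    keep = start < end
    out = intervals.loc[keep].copy()
    out["start"] = start[keep]
    out["end"] = end[keep]
    return out.reset_index(drop=True)


def durations_by_activity(
    intervals: pd.DataFrame, window: AnalysisWindow, activity_set=ACTIVITIES
) -> dict[str, float]:
    """Total seconds per label inside the window (absent labels get 0)."""
    clipped = clip_to_window(intervals, window)
    seconds = (clipped["end"] - clipped["start"]).dt.total_seconds()
    sums = seconds.groupby(clipped["label"]).sum()
    return {label: float(sums.get(label, 0.0)) for label in activity_set}


def rri_by_activity(
    rri: pd.DataFrame, intervals: pd.DataFrame, window: AnalysisWindow
) -> dict[str, list[pd.DataFrame]]:
    """Slice an RRI series by activity within a window.

    Each sample belongs to the interval containing its timestamp under the
    half-open convention [start, end): a sample at an interval's exact end
    belongs to the following interval, if any.  Samples falling in log gaps
    stay unassigned.

    Returns a map label -> list of per-occurrence segments (time-ordered
    DataFrames).  Segments are kept separate so Lorenz pairs are never
    formed across two occurrences of the same activity.
    """
    clipped = clip_to_window(intervals, window)
    ts = pd.to_datetime(rri["timestamp"]).to_numpy()
    out: dict[str, list[pd.DataFrame]] = {}
    for row in clipped.itertuples(index=False):
        lo = np.searchsorted(ts, np.datetime64(row.start), side="left")
        hi = np.searchsorted(ts, np.datetime64(row.end), side="left")
        if hi > lo:
            out.setdefault(row.label, []).append(rri.iloc[lo:hi])
    return out
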