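"""Per-questionnaire feature vectors for the five method variants.

One feature row is produced per (subject, date, question).  The five
variants form a cumulative chain — each adds feature families to its
predecessor:

=============  ==============================================================
baseline1      mean RRI and whole-window Lorenz area, for the last 24 h and
               the 4 h after waking (4 features)
baseline2      + sleep duration (hours of sleeping activity in the last 24 h)
previous       + Lorenz area per activity, both windows (12)
proposed1      + time per activity, both windows (12)
proposed2      + mixed-indicator products: Mixed * per-activity Lorenz area
               and Mixed * per-activity time, last-24h values (12)
=============  ==============================================================

Window anchoring keeps every feature strictly pre-questionnaire: the
morning question's 24 h window ends at the morning answer time and its
post-wake window uses the *previous* day's wake (this morning's 4 h have
not happened yet); the night question uses the same day's wake.

Features that cannot be computed (no wake event, fewer than two Lorenz
pairs) are NaN; the mask is exactly ``frame.isna()``.  Imputation is the
classifier's responsibility, inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import biosignal
from .activity import (
    ACTIVITIES,
    AnalysisWindow,
    clip_to_window,
    make_window,
    validate_intervals,
    wake_time,
)
from .biosignal import DEFAULT_MAX_GAP_S, lorenz_stats
from .errors import ValidationError
from .indicators import build_indicator_table
from .model import map_likert

VARIANTS = ("baseline1", "baseline2", "previous", "proposed1", "proposed2")

BASIC_FEATURES = ("mean_rri_24h", "mean_rri_wake4h", "lp_area_24h", "lp_area_wake4h")


def feature_names(variant: str, profile: str = "full") -> list[str]:
    """Ordered feature manifest of one method variant.

    ``profile='compact'`` drops the sleeping activity from the per-activity
    families (it is already carried by sleep duration), shrinking the
    proposed2 roster; the default ``'full'`` is the literal cumulative
    reading of the method table (41 features for proposed2).
    """
    acts = [a for a in ACTIVITIES if profile == "full" or a != "sleeping"]
    names = list(BASIC_FEATURES)
    if variant == "baseline1":
        return names
    names += ["sleep_duration_h"]
    if variant == "baseline2":
        return names
    names += [f"lp_area_24h__{a}" for a in acts]
    names += [f"lp_area_wake4h__{a}" for a in acts]
    if variant == "previous":
        return names
    names += [f"time_24h__{a}" for a in acts]
    names += [f"time_wake4h__{a}" for a in acts]
    if variant == "proposed1":
        return names
    names += [f"mixed_x_lp_area_24h__{a}" for a in acts]
    names += [f"mixed_x_time_24h__{a}" for a in acts]
    if variant == "proposed2":
        return names
    raise ValidationError(f"unknown variant {variant!r}")


class _SubjectSignal:
    """Pre-indexed RRI series of one subject for fast window slicing."""

    def __init__(self, hr: pd.DataFrame, max_gap_s: float):
        hr = hr.sort_values("timestamp", kind="stable")
        rri = biosignal.series_to_rri(hr)
        self.ts = rri["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        self.rri = rri["rri_ms"].to_numpy()
        if self.ts.size > 1:
            self.ok_pair = np.diff(self.ts) <= max_gap_s * 1e9
        else:
            self.ok_pair = np.zeros(0, dtype=bool)

    def slice(self, window: AnalysisWindow):
        lo = int(np.searchsorted(self.ts, window.start.value, side="left"))
        hi = int(np.searchsorted(self.ts, window.end.value, side="left"))
        return lo, hi

    def mean_rri(self, lo: int, hi: int):
        return float(np.mean(self.rri[lo:hi])) if hi > lo else None

    def pair_arrays(self, lo: int, hi: int):
        """Consecutive (a, b) values within [lo, hi) respecting the gap rule."""
        if hi - lo < 2:
            return None
        mask = self.ok_pair[lo : hi - 1]
        return self.rri[lo : hi - 1][mask], self.rri[lo + 1 : hi][mask]

    def area(self, segments) -> float | None:
        """Lorenz area of pooled (a, b) arrays; None below two pairs."""
        parts = [s for s in segments if s is not None and s[0].size]
        if not parts:
            return None
        a = np.concatenate([p[0] for p in parts])
        b = np.concatenate([p[1] for p in parts])
        stats = lorenz_stats(np.column_stack([a, b]))
        return None if stats is None else stats.area


def _nan(value):
    return np.nan if value is None else value


def build_dataset(
    cohort,
    variant: str = "proposed2",
    scope: str = "per_day",
    profile: str = "full",
    max_gap_s: float = DEFAULT_MAX_GAP_S,
):
    """Assemble the feature table of one variant for a whole cohort.

    Parameters
    ----------
    cohort : object with ``subjects``, ``heart_rate``, ``activities`` and
        ``answers`` DataFrames (a synthetic cohort or loaded CSV bundle).
    variant : one of :data:`VARIANTS`.
    scope : indicator normalization scope (``per_day`` or ``period``).
    profile : ``full`` or ``compact`` feature roster.

    Returns
    -------
    (frame, manifest) : frame has columns ``subject_id, date, question``
        followed by the variant's features; manifest records names and
        window conventions.  Row order is sorted by (subject, date,
        question) and rebuilding from the same inputs is bit-identical.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    answers = cohort.answers.copy()
    dup = answers.duplicated(["subject_id", "date", "question"])
    if dup.any():
        raise ValidationError(
            f"duplicate (subject, date, question) rows: {answers[dup].head().to_dict('records')}"
        )
    intervals_all = validate_intervals(cohort.activities)
    genders = cohort.subjects.set_index("subject_id")["gender"]

    signals = {
        sid: _SubjectSignal(grp, max_gap_s)
        for sid, grp in cohort.heart_rate.groupby("subject_id", sort=False)
    }
    intervals_by_subject = dict(tuple(intervals_all.groupby("subject_id", sort=False)))

    answers = answers.sort_values(["subject_id", "date", "question"], kind="stable")
    if "answered_at" in answers.columns:
        answers["answered_at"] = pd.to_datetime(answers["answered_at"])

    records = []
    indicator_raw = []
    for row in answers.itertuples(index=False):
        sid, date, question = row.subject_id, pd.Timestamp(row.date), row.question
        sig = signals.get(sid)
        intervals = intervals_by_subject.get(sid)
        if sig is None or intervals is None:
            continue
        anchor = getattr(row, "answered_at", None)
        if anchor is None or pd.isna(anchor):
            anchor = _default_anchor(question, intervals, date)
            if anchor is None:
                continue
        wake_date = date - pd.Timedelta(days=1) if question == "MQ" else date
        wake = wake_time(intervals, wake_date)

        w24 = make_window("last_24h", anchor)
        rec = {"subject_id": sid, "date": date.date().isoformat(), "question": question}
        lo, hi = sig.slice(w24)
        rec["mean_rri_24h"] = _nan(sig.mean_rri(lo, hi))
        rec["lp_area_24h"] = _nan(sig.area([sig.pair_arrays(lo, hi)]))
        clipped24 = clip_to_window(intervals, w24)
        dur24 = _durations(clipped24)
        rec["sleep_duration_h"] = dur24.get("sleeping", 0.0) / 3600.0
        per_act_24 = _per_activity(sig, clipped24)
        for a in ACTIVITIES:
            rec[f"time_24h__{a}"] = dur24.get(a, 0.0)
            rec[f"lp_area_24h__{a}"] = _nan(per_act_24.get(a))

        if wake is None:
            rec["mean_rri_wake4h"] = np.nan
            rec["lp_area_wake4h"] = np.nan
            for a in ACTIVITIES:
                rec[f"time_wake4h__{a}"] = np.nan
                rec[f"lp_area_wake4h__{a}"] = np.nan
        else:
            w4 = make_window("post_wake_4h", wake)
            lo4, hi4 = sig.slice(w4)
            rec["mean_rri_wake4h"] = _nan(sig.mean_rri(lo4, hi4))
            rec["lp_area_wake4h"] = _nan(sig.area([sig.pair_arrays(lo4, hi4)]))
            clipped4 = clip_to_window(intervals, w4)
            dur4 = _durations(clipped4)
            per_act_4 = _per_activity(sig, clipped4)
            for a in ACTIVITIES:
                rec[f"time_wake4h__{a}"] = dur4.get(a, 0.0)
                rec[f"lp_area_wake4h__{a}"] = _nan(per_act_4.get(a))

        records.append(rec)
        for a in ACTIVITIES:
            indicator_raw.append(
                {
                    "subject_id": sid,
                    "date": rec["date"],
                    "question": question,
                    "activity": a,
                    "gender": genders.get(sid, "F"),
                    "Ar": rec[f"time_24h__{a}"] / 86400.0,
                    "Br": rec[f"lp_area_24h__{a}"],
                }
            )

    frame = pd.DataFrame.from_records(records)
    if frame.empty:
        raise ValidationError("no feature rows could be built from the cohort")

    table = build_indicator_table(pd.DataFrame.from_records(indicator_raw), scope=scope)
    mixed = table.pivot_table(
        index=["subject_id", "date", "question"], columns="activity",
        values="Mixed", dropna=False,
    )
    keyed = frame.set_index(["subject_id", "date", "question"])
    for a in ACTIVITIES:
        mx = mixed[a].reindex(keyed.index)
        keyed[f"mixed_x_lp_area_24h__{a}"] = mx * keyed[f"lp_area_24h__{a}"]
        keyed[f"mixed_x_time_24h__{a}"] = mx * keyed[f"time_24h__{a}"]
    frame = keyed.reset_index()

    names = feature_names(variant, profile)
    out = frame[["subject_id", "date", "question"] + names].copy()
    manifest = {
        "variant": variant,
        "profile": profile,
        "n_features": len(names),
        "feature_names": names,
        "scope": scope,
        "max_gap_s": max_gap_s,
        "windows": {
            "last_24h": "anchored at the questionnaire answer time",
            "post_wake_4h": "previous day's wake for MQ, same day's wake for NQ",
        },
    }
    return out, manifest


def _default_anchor(question, intervals, date):
    """Fallback anchors when the answers file has no answered_at column:
    the morning answer at wake, the night answer at bedtime."""
    if question == "MQ":
        return wake_time(intervals, date)
    night = intervals[
        (intervals["label"] == "sleeping")
        & (intervals["start"] >= date + pd.Timedelta(hours=14))
        & (intervals["start"] < date + pd.Timedelta(hours=30))
    ]
    return night["start"].min() if len(night) else None


def _durations(clipped: pd.DataFrame) -> dict[str, float]:
    seconds = (clipped["end"] - clipped["start"]).dt.total_seconds()
    return seconds.groupby(clipped["label"]).sum().to_dict()


def _per_activity(sig: _SubjectSignal, clipped: pd.DataFrame) -> dict[str, float | None]:
    """Per-label pooled Lorenz area; pairs never cross occurrence segments."""
    segments: dict[str, list] = {}
    starts = clipped["start"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    ends = clipped["end"].to_numpy().astype("datetime64[ns]").astype(np.int64)
    labels = clipped["label"].to_numpy()
    for s, e, lab in zip(starts, ends, labels):
        lo = int(np.searchsorted(sig.ts, s, side="left"))
        hi = int(np.searchsorted(sig.ts, e, side="left"))
        pairs = sig.pair_arrays(lo, hi)
        if pairs is not None:
            segments.setdefault(lab, []).append(pairs)
    return {lab: sig.area(segs) for lab, segs in segments.items()}


def build_labels(answers: pd.DataFrame, mapping=None) -> pd.DataFrame:
    """Map Likert answers to 3-level stress labels, aligned with features.

    Returns columns ``subject_id, date, question, label`` in the same sort
    order as :func:`build_dataset` rows.
    """
    out = answers.sort_values(["subject_id", "date", "question"], kind="stable").copy()
    out["label"] = [
        map_likert(a, q, mapping) for a, q in zip(out["answer"], out["question"])
    ]
    out["date"] = [pd.Timestamp(d).date().isoformat() for d in out["date"]]
    return out[["subject_id", "date", "question", "label"]].reset_index(drop=True)


def assemble(cohort, variants=VARIANTS, scope="per_day", profile="full",
             max_gap_s=DEFAULT_MAX_GAP_S, mapping=None):
    """Build aligned per-question datasets for several variants at once.

    The full proposed2 feature superset is computed once and column-sliced
    per variant, so all variants share identical rows.

    Returns ``(datasets, labels)`` shaped for
    :func:`adlstress.evaluation.compare_methods`:
    ``datasets[variant][question]`` is a feature DataFrame and
    ``labels[question]`` the aligned label array.
    """
    full, _ = build_dataset(cohort, "proposed2", scope=scope, profile=profile,
                            max_gap_s=max_gap_s)
    lab = build_labels(cohort.answers, mapping)
    merged = full.merge(lab, on=["subject_id", "date", "question"], how="inner")
    datasets: dict = {v: {} for v in variants}
    labels: dict = {}
    for q, grp in merged.groupby("question", sort=True):
        labels[q] = grp["label"].to_numpy()
        for v in variants:
            datasets[v][q] = grp[feature_names(v, profile)].reset_index(drop=True)
    return datasets, labels
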