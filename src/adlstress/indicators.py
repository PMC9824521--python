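"""Gender-normalized activity, biometric, and mixed indicators.

For subject *s* and activity *a*, let ``Ar`` be the fraction of the last
24 hours spent on *a* and ``Br`` the Lorenz-plot area of the RRIs recorded
during *a* in that window.  Housework time differs systematically by gender
(e.g. many men in the study population never cook), so raw values are not
comparable across the cohort; both are therefore normalized within gender:

    Ai[s, a] = Ar[s, a] / mean_n(Ar[n, a])      (n over same-gender subjects)
    Bi[s, a] = Br[s, a] / mean_n(Br[n, a])

and the mixed indicator combines time share and stress intensity:

    Mixed[s, a] = Ai[s, a] * Bi[s, a]

Group means include zero participation (Ar = 0 counts; an undefined Br from
an activity with no pairs is treated as 0), so within each (gender,
activity) group the mean of Ai — and of Bi — is exactly 1 whenever defined.

Two normalization scopes are supported: ``per_day`` (default) divides each
subject-day value by the same-day group mean, keeping every indicator
computable from data available on that day; ``period`` divides by the group
mean of subjects' whole-study averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

SCOPES = ("per_day", "period")


def activity_ratio(durations: dict[str, float]) -> dict[str, float]:
    """Time share of each activity within a 24 h window: seconds / 86400."""
    return {label: seconds / 86400.0 for label, seconds in durations.items()}


def normalize_over_subjects(values: pd.Series, groups: pd.Series) -> pd.Series:
    """Divide each subject's value by its gender-group mean.

    ``values`` is indexed by subject; ``groups`` maps the same index to a
    group id.  NaN inputs count as 0 toward the group mean and normalize to
    0 (zero participation).  A zero group mean leaves the whole group
    undefined (NaN).
    """
    filled = values.fillna(0.0)
    means = filled.groupby(groups).transform("mean")
    out = filled / means.where(means != 0.0, np.nan)
    out.name = values.name
    return out


def mixed_indicator(ai, bi):
    """Elementwise product Ai * Bi; an undefined factor propagates."""
    return ai * bi


def build_indicator_table(raw: pd.DataFrame, scope: str = "per_day") -> pd.DataFrame:
    """Attach Ai, Bi, Mixed to a long table of raw per-row indicators.

    Parameters
    ----------
    raw : DataFrame with columns ``subject_id, date, question, activity,
        gender, Ar, Br``.  One row per (subject, day, question, activity);
        Br may be NaN when the activity produced fewer than two Lorenz
        pairs in the window (treated as area 0 for normalization).
    scope : ``per_day`` normalizes within each (date, question, gender,
        activity) cell; ``period`` normalizes by group means of subjects'
        period averages.

    Returns the input plus ``Ai``, ``Bi``, ``Mixed`` columns.
    """
    if scope not in SCOPES:
        raise ValidationError(f"scope must be one of {SCOPES}, got {scope!r}")
    required = {"subject_id", "date", "question", "activity", "gender", "Ar", "Br"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"indicator input missing columns {sorted(missing)}")
    out = raw.copy()
    ar = out["Ar"].fillna(0.0)
    br = out["Br"].fillna(0.0)
    if scope == "per_day":
        keys = [out["date"], out["question"], out["gender"], out["activity"]]
        ar_mean = ar.groupby(keys).transform("mean")
        br_mean = br.groupby(keys).transform("mean")
    else:
        # Per-subject period means, then the gender-group mean of those.
        subj_keys = [out["subject_id"], out["gender"], out["activity"]]
        ar_subj = ar.groupby(subj_keys).transform("mean")
        br_subj = br.groupby(subj_keys).transform("mean")
        # Average the per-subject means with equal subject weight.
        group = [out["gender"], out["activity"]]
        ar_mean = _mean_of_subject_means(ar_subj, out, group)
        br_mean = _mean_of_subject_means(br_subj, out, group)
    out["Ai"] = ar / ar_mean.where(ar_mean != 0.0, np.nan)
    out["Bi"] = br / br_mean.where(br_mean != 0.0, np.nan)
    out["Mixed"] = out["Ai"] * out["Bi"]
    return out


def _mean_of_subject_means(subj_means: pd.Series, frame: pd.DataFrame, group) -> pd.Series:
    """Group mean giving each subject weight 1 regardless of its day count."""
    tmp = frame[["subject_id", "gender", "activity"]].copy()
    tmp["value"] = subj_means
    per_subject = tmp.drop_duplicates(["subject_id", "gender", "activity"])
    means = per_subject.groupby(["gender", "activity"])["value"].mean()
    keyed = pd.MultiIndex.from_frame(frame[["gender", "activity"]])
    return pd.Series(means.reindex(keyed).to_numpy(), index=frame.index)
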