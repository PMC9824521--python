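"""CSV readers/writers for the four cohort schemas.

* ``subjects.csv``   — subject_id, gender (M|F), household_id
* ``heart_rate.csv`` — subject_id, timestamp (ISO 8601), bpm
* ``activities.csv`` — subject_id, start, end, label
* ``answers.csv``    — subject_id, date, question (MQ|NQ), answer (1-5)
                       [, answered_at]
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .activity import validate_intervals
from .errors import ValidationError


@dataclass
class CohortData:
    """A loaded cohort: the four frames the pipeline consumes."""

    subjects: pd.DataFrame
    heart_rate: pd.DataFrame
    activities: pd.DataFrame
    answers: pd.DataFrame


def load_cohort(directory) -> CohortData:
    """Load and validate a cohort directory written by the simulator or
    assembled by hand."""
    d = Path(directory)
    subjects = pd.read_csv(d / "subjects.csv", dtype={"subject_id": str})
    if not {"subject_id", "gender", "household_id"} <= set(subjects.columns):
        raise ValidationError("subjects.csv needs subject_id, gender, household_id")
    hr = pd.read_csv(d / "heart_rate.csv", dtype={"subject_id": str})
    hr["timestamp"] = pd.to_datetime(hr["timestamp"])
    activities = validate_intervals(pd.read_csv(d / "activities.csv", dtype={"subject_id": str}))
    answers = pd.read_csv(d / "answers.csv", dtype={"subject_id": str})
    if not {"subject_id", "date", "question", "answer"} <= set(answers.columns):
        raise ValidationError("answers.csv needs subject_id, date, question, answer")
    if "answered_at" in answers.columns:
        answers["answered_at"] = pd.to_datetime(answers["answered_at"])
    return CohortData(subjects=subjects, heart_rate=hr, activities=activities, answers=answers)


def write_features(frame: pd.DataFrame, manifest: dict, csv_path, manifest_path=None) -> None:
    """Write a feature table plus its companion JSON manifest."""
    csv_path = Path(csv_path)
    frame.to_csv(csv_path, index=False)
    if manifest_path is None:
        manifest_path = csv_path.with_suffix(".manifest.json")
    Path(manifest_path).write_text(json.dumps(manifest, indent=2))
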