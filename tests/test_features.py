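"""Feature-vector assembly for the five method variants."""

import numpy as np
import pandas as pd
import pytest

import adlstress as a
from adlstress.features import feature_names

from conftest import small_config


def _constant_hr_cohort(bpm=60.0):
    """Two hand-built days of constant heart rate for one subject."""
    day1 = pd.Timestamp("2022-01-01")
    day2 = pd.Timestamp("2022-01-02")
    rows = []
    for day in (day1, day2):
        rows += [
            ("S01", day, day + pd.Timedelta(hours=7), "sleeping"),
            ("S01", day + pd.Timedelta(hours=7), day + pd.Timedelta(hours=8), "cooking"),
            ("S01", day + pd.Timedelta(hours=8), day + pd.Timedelta(hours=9), "eating"),
            ("S01", day + pd.Timedelta(hours=9), day + pd.Timedelta(hours=21), "other"),
            ("S01", day + pd.Timedelta(hours=21), day + pd.Timedelta(hours=21.5), "bathing"),
            ("S01", day + pd.Timedelta(hours=21.5), day + pd.Timedelta(hours=23), "other"),
            ("S01", day + pd.Timedelta(hours=23), day + pd.Timedelta(hours=24), "sleeping"),
        ]
    activities = pd.DataFrame(rows, columns=["subject_id", "start", "end", "label"])
    ts = pd.date_range(day1, day2 + pd.Timedelta(hours=24), freq="15s", inclusive="left")
    heart_rate = pd.DataFrame({"subject_id": "S01", "timestamp": ts, "bpm": bpm})
    answers = pd.DataFrame(
        {
            "subject_id": ["S01", "S01"],
            "date": ["2022-01-02", "2022-01-02"],
            "question": ["MQ", "NQ"],
            "answer": [4, 2],
            "answered_at": [day2 + pd.Timedelta(hours=7), day2 + pd.Timedelta(hours=23)],
        }
    )
    subjects = pd.DataFrame(
        {"subject_id": ["S01"], "gender": ["F"], "household_id": ["H01"]}
    )
    return a.CohortData(subjects, heart_rate, activities, answers)


def test_constant_heart_rate_basic_features():
    frame, _ = a.build_dataset(_constant_hr_cohort(), "baseline1")
    assert len(frame) == 2
    for _, row in frame.iterrows():
        assert row["mean_rri_24h"] == pytest.approx(1000.0)
        assert row["mean_rri_wake4h"] == pytest.approx(1000.0)
        assert row["lp_area_24h"] == pytest.approx(0.0, abs=1e-9)
        assert row["lp_area_wake4h"] == pytest.approx(0.0, abs=1e-9)


def test_sleep_duration_equals_sleeping_time():
    frame, _ = a.build_dataset(_constant_hr_cohort(), "proposed1")
    nq = frame[frame["question"] == "NQ"].iloc[0]
    # Window [day1 23:00, day2 23:00): sleeping 23:00-07:00 = 8 h.
    assert nq["sleep_duration_h"] == pytest.approx(8.0)
    assert nq["sleep_duration_h"] == pytest.approx(nq["time_24h__sleeping"] / 3600.0)


def test_missing_wake_masks_post_wake_features():
    cohort = _constant_hr_cohort()
    # Remove day-1 morning sleep: the MQ row (previous-day wake) loses its anchor.
    keep = ~(
        (cohort.activities["label"] == "sleeping")
        & (cohort.activities["end"] == pd.Timestamp("2022-01-01 07:00"))
    )
    cohort.activities = cohort.activities[keep].reset_index(drop=True)
    frame, _ = a.build_dataset(cohort, "baseline1")
    mq = frame[frame["question"] == "MQ"].iloc[0]
    nq = frame[frame["question"] == "NQ"].iloc[0]
    assert np.isnan(mq["mean_rri_wake4h"]) and np.isnan(mq["lp_area_wake4h"])
    assert not np.isnan(nq["mean_rri_wake4h"])


def test_variant_feature_counts_and_nesting():
    counts = {"baseline1": 4, "baseline2": 5, "previous": 17,
              "proposed1": 29, "proposed2": 41}
    previous: set = set()
    for variant in a.VARIANTS:
        names = feature_names(variant)
        assert len(names) == counts[variant]
        assert previous <= set(names)  # cumulative chain
        previous = set(names)


def test_compact_profile_drops_sleeping_from_activity_families():
    names = feature_names("proposed2", profile="compact")
    assert len(names) == 41 - 6
    assert "lp_area_24h__sleeping" not in names
    assert "sleep_duration_h" in names  # still carried by its own family


def test_manifest_reports_roster(small_cohort):
    _, manifest = a.build_dataset(small_cohort, "proposed2", max_gap_s=120)
    assert manifest["n_features"] == 41
    assert manifest["feature_names"] == feature_names("proposed2")


def test_rebuild_is_bit_identical(small_cohort):
    f1, _ = a.build_dataset(small_cohort, "proposed2", max_gap_s=120)
    f2, _ = a.build_dataset(small_cohort, "proposed2", max_gap_s=120)
    pd.testing.assert_frame_equal(f1, f2)
    assert f1.to_csv(index=False) == f2.to_csv(index=False)


def test_duplicate_answer_rows_rejected():
    cohort = _constant_hr_cohort()
    cohort.answers = pd.concat([cohort.answers, cohort.answers.iloc[[0]]],
                               ignore_index=True)
    with pytest.raises(a.ValidationError, match="duplicate"):
        a.build_dataset(cohort, "baseline1")


def test_single_subject_mixed_features_equal_raw(rng):
    """One subject per gender group: Ai = Bi = 1, so the mixed products
    reproduce the raw per-activity features wherever defined."""
    cohort = _constant_hr_cohort()
    cohort.heart_rate = cohort.heart_rate.assign(
        bpm=np.round(rng.uniform(55, 85, len(cohort.heart_rate)), 2)
    )
    frame, _ = a.build_dataset(cohort, "proposed2")
    for _, row in frame.iterrows():
        for act in a.ACTIVITIES:
            raw_area = row[f"lp_area_24h__{act}"]
            raw_time = row[f"time_24h__{act}"]
            if raw_time > 0 and not np.isnan(raw_area) and raw_area > 0:
                assert row[f"mixed_x_lp_area_24h__{act}"] == pytest.approx(raw_area)
                assert row[f"mixed_x_time_24h__{act}"] == pytest.approx(raw_time)


def test_features_match_manual_composition_oracle():
    """One row's basic features recomputed from the low-level operations."""
    config = small_config(n_households=1, singles_fraction=0.0, n_days=2,
                          hr_sample_period=15, seed=31)
    cohort = a.simulate_cohort(config)
    frame, _ = a.build_dataset(cohort, "proposed1")
    row = frame[(frame["question"] == "NQ") & (frame["date"] == "2023-03-02")].iloc[0]
    sid = row["subject_id"]
    answers = cohort.answers
    anchor = answers[
        (answers["subject_id"] == sid)
        & (answers["date"] == "2023-03-02")
        & (answers["question"] == "NQ")
    ]["answered_at"].iloc[0]
    hr = cohort.heart_rate[cohort.heart_rate["subject_id"] == sid]
    rri = a.series_to_rri(hr.sort_values("timestamp"))
    window = a.make_window("last_24h", anchor)
    in_window = rri[(rri["timestamp"] >= window.start) & (rri["timestamp"] < window.end)]
    assert row["mean_rri_24h"] == pytest.approx(a.mean_rri(in_window), rel=1e-12)
    assert row["lp_area_24h"] == pytest.approx(
        a.lorenz_stats(a.build_pairs(in_window)).area, rel=1e-9
    )
    intervals = cohort.activities[cohort.activities["subject_id"] == sid]
    durations = a.durations_by_activity(intervals, window)
    for act in a.ACTIVITIES:
        assert row[f"time_24h__{act}"] == pytest.approx(durations[act], abs=1e-6)
    # Per-activity area for sleeping: pooled per-segment pairs.
    segments = a.rri_by_activity(rri, intervals, window)["sleeping"]
    pairs = np.vstack([a.build_pairs(seg) for seg in segments])
    assert row["lp_area_24h__sleeping"] == pytest.approx(
        a.lorenz_stats(pairs).area, rel=1e-9
    )


def test_assemble_aligns_labels_and_features(small_cohort):
    datasets, labels = a.assemble(small_cohort, max_gap_s=120)
    for q in ("MQ", "NQ"):
        for variant in a.VARIANTS:
            assert len(datasets[variant][q]) == len(labels[q])
        assert set(np.unique(labels[q])) <= set(a.CLASSES)
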