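"""Interval parsing, analysis windows, clipping and per-activity slicing."""

import numpy as np
import pandas as pd
import pytest

import adlstress as a
from adlstress.activity import validate_intervals

from conftest import TABLE1_ACTIVITY_SET, TABLE1_DATE, table1_frame


def one_second_duration_oracle(intervals, window, labels):
    """Membership count at 1 s resolution — the independent reference."""
    start = int(window.start.value // 10**9)
    end = int(window.end.value // 10**9)
    seconds = np.arange(start, end)
    totals = dict.fromkeys(labels, 0)
    for row in intervals.itertuples(index=False):
        s = int(pd.Timestamp(row.start).value // 10**9)
        e = int(pd.Timestamp(row.end).value // 10**9)
        totals[row.label] += int(np.sum((seconds >= s) & (seconds < e)))
    return totals


class TestLoading:
    def test_table1_transcription_loads(self, table1_csv):
        log = a.load_activity_log(table1_csv, activity_set=TABLE1_ACTIVITY_SET)
        assert len(log) == 11
        assert list(log["label"])[:3] == ["sleeping", "cooking", "eating_meals"]

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("subject_id,start,end,label\n")
        assert len(a.load_activity_log(p)) == 0

    def test_overlap_rejected_with_row_ids(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01", "S01"],
                "start": pd.to_datetime(["2022-01-01 08:00", "2022-01-01 08:30"]),
                "end": pd.to_datetime(["2022-01-01 09:00", "2022-01-01 09:30"]),
                "label": ["cooking", "eating"],
            }
        )
        with pytest.raises(a.ValidationError, match="overlapping.*0 and 1"):
            validate_intervals(frame)

    def test_unknown_label_named(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01"],
                "start": pd.to_datetime(["2022-01-01 08:00"]),
                "end": pd.to_datetime(["2022-01-01 09:00"]),
                "label": ["juggling"],
            }
        )
        with pytest.raises(a.ValidationError, match="juggling"):
            validate_intervals(frame)


class TestWake:
    def test_table1_wake_is_seven(self):
        assert a.wake_time(table1_frame(), TABLE1_DATE) == pd.Timestamp("2022-01-01 07:00")

    def test_interrupted_night_takes_last_end(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01"] * 2,
                "start": pd.to_datetime(["2022-01-01 01:00", "2022-01-01 06:30"]),
                "end": pd.to_datetime(["2022-01-01 06:00", "2022-01-01 07:30"]),
                "label": ["sleeping", "sleeping"],
            }
        )
        assert a.wake_time(frame, "2022-01-01") == pd.Timestamp("2022-01-01 07:30")

    def test_no_sleep_returns_marker(self):
        frame = table1_frame()
        assert a.wake_time(frame[frame["label"] != "sleeping"], TABLE1_DATE) is None


class TestWindows:
    def test_last_24h_span(self):
        w = a.make_window("last_24h", "2022-01-02 22:00")
        assert w.start == pd.Timestamp("2022-01-01 22:00")
        assert (w.end - w.start).total_seconds() == 86400

    def test_post_wake_span(self):
        w = a.make_window("post_wake_4h", "2022-01-01 07:00")
        assert w.end == pd.Timestamp("2022-01-01 11:00")
        assert (w.end - w.start).total_seconds() == 14400


class TestClipping:
    def test_truncation_and_drop(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01", "S01"],
                "start": pd.to_datetime(["2022-01-01 06:00", "2022-01-01 01:00"]),
                "end": pd.to_datetime(["2022-01-01 08:00", "2022-01-01 02:00"]),
                "label": ["cooking", "other"],
            }
        )
        window = a.AnalysisWindow("last_24h", pd.Timestamp("2022-01-01 07:00"),
                                  pd.Timestamp("2022-01-01 07:00"),
                                  pd.Timestamp("2022-01-01 09:00"))
        clipped = a.clip_to_window(frame, window)
        assert len(clipped) == 1
        assert clipped.loc[0, "start"] == pd.Timestamp("2022-01-01 07:00")
        assert clipped.loc[0, "end"] == pd.Timestamp("2022-01-01 08:00")

    def test_idempotence(self, rng):
        frame = table1_frame()
        w = a.make_window("last_24h", "2022-01-01 22:00")
        once = a.clip_to_window(frame, w)
        twice = a.clip_to_window(once, w)
        pd.testing.assert_frame_equal(once, twice)

    def test_durations_match_one_second_oracle(self, rng):
        day = pd.Timestamp("2022-01-01")
        for _ in range(20):
            n = int(rng.integers(1, 8))
            bounds = np.sort(rng.choice(np.arange(0, 1440), size=2 * n, replace=False))
            labels = rng.choice(a.ACTIVITIES, size=n)
            frame = pd.DataFrame(
                {
                    "subject_id": "S01",
                    "start": [day + pd.Timedelta(minutes=int(b)) for b in bounds[0::2]],
                    "end": [day + pd.Timedelta(minutes=int(b)) for b in bounds[1::2]],
                    "label": labels,
                }
            )
            anchor = day + pd.Timedelta(minutes=int(rng.integers(60, 1440)))
            window = a.make_window("last_24h", anchor)
            got = a.durations_by_activity(frame, window)
            want = one_second_duration_oracle(frame, window, a.ACTIVITIES)
            assert got == pytest.approx(want)

    def test_empty_and_bounded(self):
        w = a.make_window("last_24h", "2022-01-02 00:00")
        empty = a.durations_by_activity(table1_frame().iloc[:0], w)
        assert set(empty.values()) == {0.0}
        full = a.durations_by_activity(table1_frame(), w, TABLE1_ACTIVITY_SET)
        assert sum(full.values()) <= 86400 + 1e-9

    def test_table1_sleeping_total_midnight_window(self):
        w = a.make_window("last_24h", "2022-01-02 00:00")
        durations = a.durations_by_activity(table1_frame(), w, TABLE1_ACTIVITY_SET)
        # 00:00-07:00 plus 23:00-24:00 -> 8 hours of sleeping
        assert durations["sleeping"] == pytest.approx(8 * 3600)


def _rri(seconds):
    return pd.DataFrame(
        {"timestamp": pd.Timestamp("2022-01-01") + pd.to_timedelta(seconds, unit="s"),
         "rri_ms": 1000.0 + np.arange(len(seconds))}
    )


class TestRriByActivity:
    def test_half_open_boundary(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01", "S01"],
                "start": pd.to_datetime(["2022-01-01 00:00", "2022-01-01 01:00"]),
                "end": pd.to_datetime(["2022-01-01 01:00", "2022-01-01 02:00"]),
                "label": ["cooking", "eating"],
            }
        )
        w = a.make_window("last_24h", "2022-01-02 00:00")
        rri = _rri([3600])  # exactly the boundary instant
        out = a.rri_by_activity(rri, frame, w)
        assert "cooking" not in out
        assert len(out["eating"]) == 1 and len(out["eating"][0]) == 1

    def test_two_segments_pool_without_cross_pairs(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["S01", "S01"],
                "start": pd.to_datetime(["2022-01-01 00:00", "2022-01-01 02:00"]),
                "end": pd.to_datetime(["2022-01-01 01:00", "2022-01-01 03:00"]),
                "label": ["cooking", "cooking"],
            }
        )
        w = a.make_window("last_24h", "2022-01-02 00:00")
        seg1 = np.arange(0, 3600, 15)
        seg2 = np.arange(7200, 10800, 15)
        rri = _rri(np.concatenate([seg1, seg2]))
        out = a.rri_by_activity(rri, frame, w)
        assert len(out["cooking"]) == 2
        n1, n2 = len(seg1), len(seg2)
        total_pairs = sum(
            a.build_pairs(seg).shape[0] for seg in out["cooking"]
        )
        assert total_pairs == (n1 - 1) + (n2 - 1)

    def test_assignment_matches_linear_scan_oracle(self, rng):
        frame = table1_frame()
        w = a.make_window("last_24h", "2022-01-02 00:00")
        seconds = np.sort(rng.choice(np.arange(0, 86400, 5), size=400, replace=False))
        rri = _rri(seconds)
        out = a.rri_by_activity(rri, frame, w)
        # Oracle: per-sample scan over intervals.
        assigned = {}
        for sec in seconds:
            t = pd.Timestamp("2022-01-01") + pd.Timedelta(seconds=int(sec))
            for row in frame.itertuples(index=False):
                if row.start <= t < row.end:
                    assigned.setdefault(row.label, []).append(t)
                    break
        got = {
            label: [ts for seg in segs for ts in seg["timestamp"]]
            for label, segs in out.items()
        }
        assert {k: sorted(v) for k, v in got.items()} == {
            k: sorted(v) for k, v in assigned.items()
        }

    def test_partition_property(self, rng):
        frame = table1_frame()
        w = a.make_window("last_24h", "2022-01-02 00:00")
        seconds = np.sort(rng.choice(np.arange(0, 86400, 7), size=600, replace=False))
        rri = _rri(seconds)
        out = a.rri_by_activity(rri, frame, w)
        assigned = sum(len(seg) for segs in out.values() for seg in segs)
        # Table 1 has a 07:00-07:30 hole; samples there stay unassigned.
        hole = np.sum((seconds >= 7 * 3600) & (seconds < 7.5 * 3600))
        assert assigned + hole == len(seconds)
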