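"""DAR extraction: fix filtering, diel segmentation, night quality,
flight/stop segmentation, endpoint averaging and subsampling."""

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

import darshape as ds
from conftest import make_track


LOCAL_NOON_UTC = datetime(2021, 3, 1, 10, 0, tzinfo=timezone.utc)  # 12:00 IST


class TestFilterFixes:
    def test_high_std_fix_removed(self):
        track = make_track("a", [0, 10, 20], [0, 1, 2], [0, 0, 0],
                           std=[5, 60, 5])
        out, counts = ds.filter_fixes(track)
        assert counts == {"std": 1, "speed": 0}
        assert list(out.fixes["x"]) == [0.0, 2.0]

    def test_speed_rule_removes_20_m_per_s_jump(self):
        # 200 m in 10 s = 20 m/s > 15
        track = make_track("a", [0, 10, 20], [0, 200, 210], [0, 0, 0])
        out, counts = ds.filter_fixes(track)
        assert counts["speed"] == 1
        assert list(out.fixes["x"]) == [0.0, 210.0]  # third ok vs first: 10.5 m/s

    def test_speed_compared_to_last_retained_fix(self):
        # after dropping the jump, the next fix is judged against fix 0
        track = make_track("a", [0, 10, 12], [0, 200, 400], [0, 0, 0])
        out, counts = ds.filter_fixes(track)
        assert counts["speed"] == 2
        assert list(out.fixes["x"]) == [0.0]

    def test_empty_track(self):
        track = make_track("a", [], [], [])
        out, counts = ds.filter_fixes(track)
        assert len(out) == 0 and counts == {"std": 0, "speed": 0}

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        n = 400
        x = np.cumsum(rng.normal(0, 30, n))
        x[rng.choice(n, 20, replace=False)] += 2000  # inject jumps
        track = make_track("a", np.arange(n) * 8.0, x, np.zeros(n))
        out, _ = ds.filter_fixes(track)
        t = out.fixes["timestamp"].astype("int64").to_numpy() / 1e9
        d = np.abs(np.diff(out.fixes["x"].to_numpy()))
        assert np.all(d / np.diff(t) <= 15.0 + 1e-9)


class TestSegmentNights:
    def test_before_boundary_belongs_to_previous_night(self):
        t0 = datetime(2021, 3, 2, 7, 59, tzinfo=timezone.utc)  # 09:59 local
        track = make_track("a", [0], [0], [0], t0=t0)
        nights = ds.segment_nights(track)
        assert nights[0].night_date == date(2021, 3, 1)

    def test_boundary_fix_opens_new_night(self):
        t0 = datetime(2021, 3, 2, 8, 0, tzinfo=timezone.utc)  # 10:00 local
        track = make_track("a", [0], [0], [0], t0=t0)
        assert ds.segment_nights(track)[0].night_date == date(2021, 3, 2)

    def test_partition_preserves_all_fixes(self):
        n = 3 * 24 * 6  # 3 days at 10-min cadence
        track = make_track("a", np.arange(n) * 600.0, np.arange(n), np.zeros(n),
                           t0=LOCAL_NOON_UTC)
        nights = ds.segment_nights(track)
        assert 3 <= len(nights) <= 4
        got = sorted(x for night in nights for x in night.fixes["x"])
        assert got == list(range(n))


class TestNightQuality:
    def _night(self, n_fixes, start_hour_utc, end_hour_offset):
        t0 = datetime(2021, 3, 1, start_hour_utc, 0, tzinfo=timezone.utc)
        span = end_hour_offset * 3600
        track = make_track("a", np.linspace(0, span, n_fixes),
                           np.zeros(n_fixes), np.zeros(n_fixes), t0=t0)
        return ds.segment_nights(track)[0]

    def test_count_rule_is_strict(self):
        night = self._night(999, 16, 10)  # 18:00-04:00 local
        ok, reasons = ds.night_is_complete(night, min_fixes=1000)
        assert not ok and any("count" in r for r in reasons)
        assert ds.night_is_complete(self._night(1001, 16, 10))[0]

    def test_late_start_fails(self):
        t0 = datetime(2021, 3, 1, 19, 30, tzinfo=timezone.utc)  # 21:30 local
        track = make_track("a", np.linspace(0, 8 * 3600, 1500),
                           np.zeros(1500), np.zeros(1500), t0=t0)
        night = ds.segment_nights(track)[0]
        ok, reasons = ds.night_is_complete(night)
        assert not ok and any("start" in r for r in reasons)

    def test_early_end_fails(self):
        t0 = datetime(2021, 3, 1, 16, 0, tzinfo=timezone.utc)  # 18:00 local
        track = make_track("a", np.linspace(0, 6 * 3600, 1500),  # ends 00:00
                           np.zeros(1500), np.zeros(1500), t0=t0)
        night = ds.segment_nights(track)[0]
        ok, reasons = ds.night_is_complete(night)
        assert not ok and any("end" in r for r in reasons)

    def test_good_night_passes(self):
        night = self._night(1500, 16, 12)  # 18:00 -> 06:00 local
        assert ds.night_is_complete(night) == (True, [])


class TestSelectIndividuals:
    def test_strictly_greater_than_threshold(self):
        counts = {"a": 30, "b": 31, "c": 50}
        assert ds.select_individuals(counts, 30) == {"b", "c"}

    def test_empty_cohort(self):
        assert ds.select_individuals({}, 30) == set()


def _night_from_xy(x, y, dt_s=8.0):
    n = len(x)
    track = make_track("a", np.arange(n) * dt_s, x, y, t0=LOCAL_NOON_UTC)
    return ds.segment_nights(track)[0]


class TestFlightSegmentation:
    def test_stationary_night_is_single_stop(self):
        rng = np.random.default_rng(0)
        night = _night_from_xy(rng.normal(0, 2, 500), rng.normal(0, 2, 500))
        segs = ds.detect_flight_segments(night)
        assert [s.label for s in segs] == ["stop"]
        assert (segs[0].first_index, segs[0].last_index) == (0, 499)

    def test_single_flight_detected_within_window(self):
        # 2 h stop, 20-min straight flight at 8 m/s, 2 h stop (8 s cadence)
        rng = np.random.default_rng(1)
        n_stop, n_fly = 900, 150
        x = np.concatenate([
            np.zeros(n_stop),
            np.cumsum(np.full(n_fly, 64.0)),     # 8 m/s * 8 s
            np.full(n_stop, n_fly * 64.0),
        ]) + rng.normal(0, 2, 2 * n_stop + n_fly)
        night = _night_from_xy(x, np.zeros_like(x))
        segs = ds.detect_flight_segments(night)
        moves = [s for s in segs if s.label == "move"]
        assert len(moves) == 1
        tol = 60 / 8 + 1  # window length in fixes
        assert abs(moves[0].first_index - n_stop) <= tol
        assert abs(moves[0].last_index - (n_stop + n_fly)) <= tol

    def test_two_flights_give_two_move_segments(self):
        rng = np.random.default_rng(2)
        stop = np.zeros(450)  # 1 h
        fly = np.cumsum(np.full(120, 48.0))  # 16 min at 6 m/s
        x = np.concatenate([stop, fly, fly[-1] + stop, fly[-1] + fly,
                            np.full(450, 2 * fly[-1])])
        x = x + rng.normal(0, 2, len(x))
        night = _night_from_xy(x, np.zeros_like(x))
        moves = [s for s in ds.detect_flight_segments(night)
                 if s.label == "move"]
        assert len(moves) == 2

    def test_partition_is_contiguous_and_alternating(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([np.zeros(300), np.cumsum(np.full(100, 50.0)),
                            np.full(300, 5000.0)]) + rng.normal(0, 2, 700)
        night = _night_from_xy(x, np.zeros_like(x))
        segs = ds.detect_flight_segments(night)
        assert segs[0].first_index == 0 and segs[-1].last_index == len(night) - 1
        for a, b in zip(segs, segs[1:]):
            assert b.first_index == a.last_index + 1
            assert a.label != b.label

    def test_tiny_night_is_single_stop(self):
        night = _night_from_xy([0.0], [0.0])
        assert [s.label for s in ds.detect_flight_segments(night)] == ["stop"]


class TestEndpoints:
    def _night_with_flight_at(self, first_move_index, n_total=200):
        x = np.zeros(n_total)
        x[first_move_index:first_move_index + 40] = np.cumsum(
            np.full(40, 40.0))
        x[first_move_index + 40:] = x[first_move_index + 39]
        return _night_from_xy(x, np.zeros(n_total))

    def test_start_is_mean_of_n_fixes_before_first_move(self):
        xy = np.zeros((100, 2))
        xy[:25, 0] = np.arange(25, dtype=float)  # fixes 5..24 mean = 14.5
        night = _night_from_xy(xy[:, 0], xy[:, 1])
        segs = [ds.FlightSegment(0, 0, 24, "stop"),
                ds.FlightSegment(1, 25, 60, "move"),
                ds.FlightSegment(2, 61, 99, "stop")]
        start, end, no_flight = ds.extract_endpoints(night, segs, n=20)
        assert not no_flight
        assert start == pytest.approx((14.5, 0.0))

    def test_too_few_fixes_before_first_move_gives_missing(self):
        night = self._night_with_flight_at(10)
        segs = [ds.FlightSegment(0, 0, 9, "stop"),
                ds.FlightSegment(1, 10, 49, "move"),
                ds.FlightSegment(2, 50, 199, "stop")]
        start, end, _ = ds.extract_endpoints(night, segs, n=20)
        assert start is None and end is not None

    def test_constant_roost_recovered_exactly(self):
        x = np.full(100, 100.0)
        y = np.full(100, 200.0)
        night = _night_from_xy(x, y)
        segs = [ds.FlightSegment(0, 0, 39, "stop"),
                ds.FlightSegment(1, 40, 59, "move"),
                ds.FlightSegment(2, 60, 99, "stop")]
        start, end, _ = ds.extract_endpoints(night, segs, n=20)
        assert start == pytest.approx((100.0, 200.0))
        assert end == pytest.approx((100.0, 200.0))

    def test_no_flight_night_flagged_and_uses_track_ends(self):
        night = _night_from_xy(np.arange(100, dtype=float), np.zeros(100))
        segs = [ds.FlightSegment(0, 0, 99, "stop")]
        start, end, no_flight = ds.extract_endpoints(night, segs, n=20)
        assert no_flight
        assert start == pytest.approx((np.arange(20).mean(), 0.0))
        assert end == pytest.approx((np.arange(80, 100).mean(), 0.0))


class TestSubsample:
    def test_4s_fixes_over_an_hour_at_5min_gives_12_points(self):
        n = 900  # 4 s cadence, 1 h
        night = _night_from_xy(np.arange(n, dtype=float), np.zeros(n), dt_s=4.0)
        out = ds.subsample(night, 300.0)
        assert len(out) == 12

    def test_interval_below_fix_spacing_is_identity(self):
        night = _night_from_xy(np.arange(50, dtype=float), np.zeros(50), dt_s=8.0)
        out = ds.subsample(night, 4.0)
        assert len(out) == 50

    def test_single_fix(self):
        night = _night_from_xy([7.0], [0.0])
        out = ds.subsample(night)
        assert len(out) == 1 and out["x"].iloc[0] == 7.0

    def test_output_is_subsequence_and_idempotent(self):
        night = _night_from_xy(np.arange(300, dtype=float), np.zeros(300))
        out = ds.subsample(night, 120.0)
        xs = set(night.fixes["x"])
        assert all(x in xs for x in out["x"])
        # re-subsampling at the same interval keeps every point
        night2 = _night_from_xy(out["x"].to_numpy(), out["y"].to_numpy(),
                                dt_s=120.0)
        out2 = ds.subsample(night2, 120.0)
        assert len(out2) == len(out)


class TestBuildDars:
    def test_generated_complete_nights_become_dars(self, small_cohort):
        tracks_df, meta_df, truth, cfg = small_cohort
        from darshape.pipeline import frame_to_tracks
        dars, report = ds.build_dars(frame_to_tracks(tracks_df), None, cfg)
        assert len(dars) == len(truth)
        assert report["dars"] == len(dars)
        assert report["nights_complete"] == len(truth)

    def test_individual_below_night_threshold_excluded(self, small_cohort):
        tracks_df, meta_df, truth, _ = small_cohort
        from darshape.pipeline import frame_to_tracks
        cfg = ds.RunConfig(min_nights=5)  # both individuals have exactly 5
        dars, report = ds.build_dars(frame_to_tracks(tracks_df), None, cfg)
        assert dars == []
        assert report["individuals_selected"] == []

    def test_deterministic_for_identical_inputs(self, small_cohort):
        tracks_df, _, _, cfg = small_cohort
        from darshape.pipeline import frame_to_tracks
        from darshape.dar_extraction import dars_to_frames
        d1, _ = ds.build_dars(frame_to_tracks(tracks_df), None, cfg)
        d2, _ = ds.build_dars(frame_to_tracks(tracks_df.copy()), None, cfg)
        f1, p1 = dars_to_frames(d1)
        f2, p2 = dars_to_frames(d2)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(p1, p2)
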