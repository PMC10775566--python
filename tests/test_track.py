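import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmcp.track import (
    Track,
    check_gaps,
    compute_steps,
    filter_dop,
    rarefy_daily,
    read_track_csv,
    split_at_southernmost,
    subset_dates,
)

from conftest import straight_track


def _write_csv(path, rows, header="id,timestamp,x,y"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadTrackCsv:
    def test_rows_sorted_by_time(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["a,2020-01-03,3,0", "a,2020-01-01,1,0", "a,2020-01-02,2,0"])
        (track,) = read_track_csv(f)
        assert np.all(np.diff(track.times) > 0)
        assert track.x.tolist() == [1, 2, 3]

    def test_two_ids_partition_rows(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["a,1.0,0,0", "b,1.0,1,1", "a,2.0,0,1", "b,2.0,1,2", "a,3.0,0,2"])
        tracks = read_track_csv(f)
        assert sorted(t.id for t in tracks) == ["a", "b"]
        assert sum(len(t) for t in tracks) == 5

    def test_duplicate_timestamps_collapse_to_first(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["a,1.0,0,0", "a,2.0,5,5", "a,2.0,9,9", "a,3.0,1,1"])
        (track,) = read_track_csv(f)
        assert len(track) == 3
        assert track.x[1] == 5  # first occurrence kept

    def test_missing_column_errors(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("id,timestamp,x\na,1.0,0\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_track_csv(f)

    def test_unparseable_timestamp_names_row(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["a,2020-01-01,0,0", "a,not-a-date,1,1"])
        with pytest.raises(ValueError, match="row 1"):
            read_track_csv(f)

    def test_numeric_timestamps_pass_through(self, tmp_path):
        f = tmp_path / "t.csv"
        _write_csv(f, ["a,0.5,0,0", "a,1.5,1,1"])
        (track,) = read_track_csv(f)
        assert track.times.tolist() == [0.5, 1.5]
        assert track.epoch is None


class TestFilterDop:
    def _track(self, hdop, vdop):
        n = len(hdop)
        return Track(id="a", times=np.arange(float(n)), x=np.zeros(n), y=np.zeros(n),
                     hdop=np.asarray(hdop, float), vdop=np.asarray(vdop, float))

    def test_all_within_threshold_is_identity(self):
        t = self._track([1, 2, 3], [1, 2, 3])
        assert len(filter_dop(t)) == 3

    def test_high_hdop_removed(self):
        t = self._track([1] * 9 + [6], [1] * 10)
        assert len(filter_dop(t)) == 9

    def test_either_direction_triggers_removal(self):
        t = self._track([3, 3], [7, 3])
        out = filter_dop(t)
        assert len(out) == 1 and out.vdop[0] == 3

    def test_missing_dop_retained(self):
        t = Track(id="a", times=np.arange(3.0), x=np.zeros(3), y=np.zeros(3),
                  hdop=np.array([1.0, np.nan, 9.0]))
        assert len(filter_dop(t)) == 2  # NaN kept, 9 dropped


class TestRarefyDaily:
    def test_hourly_track_keeps_one_per_day(self):
        times = np.concatenate([d + np.arange(24) / 24 for d in range(3)])
        t = Track(id="a", times=times, x=np.arange(72.0), y=np.zeros(72), dt_nominal=1 / 24)
        out = rarefy_daily(t)
        assert len(out) == 3 and out.dt_nominal == 1.0

    def test_already_daily_is_identity(self):
        t = straight_track(5)
        out = rarefy_daily(t)
        assert np.array_equal(out.times, t.times)

    def test_fix_nearest_noon_wins(self):
        # fixes at 11:00 and 14:00 on day 0
        t = Track(id="a", times=np.array([11 / 24, 14 / 24]), x=np.array([1.0, 2.0]),
                  y=np.zeros(2), dt_nominal=1 / 24)
        out = rarefy_daily(t)
        assert out.x.tolist() == [1.0]

    def test_tie_goes_to_earlier_fix(self):
        t = Track(id="a", times=np.array([11 / 24, 13 / 24]), x=np.array([1.0, 2.0]),
                  y=np.zeros(2), dt_nominal=1 / 24)
        assert rarefy_daily(t).x.tolist() == [1.0]


class TestSubsetDates:
    def test_covering_window_is_identity(self):
        t = straight_track(5)
        assert len(subset_dates(t, -1, 10)) == 5

    def test_boundaries_inclusive(self):
        t = straight_track(10)
        out = subset_dates(t, 2, 6)
        assert out.times.tolist() == [2, 3, 4, 5, 6]

    def test_disjoint_window_warns_and_empties(self):
        t = straight_track(5)
        with pytest.warns(UserWarning, match="no locations"):
            out = subset_dates(t, 100, 200)
        assert len(out) == 0


class TestCheckGaps:
    def test_small_steps_pass(self):
        assert check_gaps(straight_track(20), 400.0, 14.0).passed

    def test_spatial_jump_fails_with_pair_reported(self):
        t = Track(id="a", times=np.arange(3.0), x=np.array([0.0, 450.0, 451.0]),
                  y=np.zeros(3))
        rep = check_gaps(t, 400.0, 14.0)
        assert not rep.passed
        assert rep.spatial["displacement_km"].tolist() == [450.0]

    def test_temporal_hole_fails(self):
        t = Track(id="a", times=np.array([0.0, 1.0, 16.0]), x=np.zeros(3), y=np.zeros(3))
        rep = check_gaps(t, 400.0, 14.0)
        assert not rep.passed and len(rep.temporal) == 1

    @given(s1=st.floats(1, 500), s2=st.floats(1, 500), t1=st.floats(0.5, 20), t2=st.floats(0.5, 20))
    @settings(max_examples=50, deadline=None)
    def test_pass_fail_monotone_in_thresholds(self, s1, s2, t1, t2):
        track = Track(id="a", times=np.array([0.0, 1.0, 12.0, 13.0]),
                      x=np.array([0.0, 100.0, 100.0, 300.0]), y=np.zeros(4))
        lo = check_gaps(track, min(s1, s2), min(t1, t2)).passed
        hi = check_gaps(track, max(s1, s2), max(t1, t2)).passed
        assert (not lo) or hi  # passing at tight thresholds implies passing at loose ones


class TestSplitAtSouthernmost:
    def test_v_shaped_track_splits_at_turn(self):
        y = np.array([5.0, 3.0, 1.0, 2.0, 4.0])
        t = Track(id="a", times=np.arange(5.0), x=np.zeros(5), y=y)
        fall, spring = split_at_southernmost(t)
        assert len(fall) == 3 and len(spring) == 3
        assert fall.y[-1] == 1.0 and spring.y[0] == 1.0

    def test_tie_breaks_to_earlier_fix(self):
        y = np.array([5.0, 1.0, 2.0, 1.0, 4.0])
        t = Track(id="a", times=np.arange(5.0), x=np.zeros(5), y=y)
        fall, _ = split_at_southernmost(t)
        assert len(fall) == 2

    def test_constant_y_warns_degenerate(self):
        t = straight_track(5)  # y constant 0, min at first fix
        with pytest.warns(UserWarning, match="degenerate"):
            fall, spring = split_at_southernmost(t)
        assert len(fall) == 1

    def test_too_short_track_errors(self):
        with pytest.raises(ValueError):
            split_at_southernmost(straight_track(2))


class TestComputeSteps:
    def test_collinear_equally_spaced(self):
        t = Track(id="a", times=np.arange(3.0), x=np.array([0.0, 1.0, 2.0]), y=np.zeros(3))
        s = compute_steps(t)
        assert s.r.tolist() == [1.0, 1.0]
        assert not s.valid_phi[0] and s.valid_phi[1]
        assert s.phi[1] == pytest.approx(0.0)

    def test_right_angle_turn(self):
        t = Track(id="a", times=np.arange(3.0), x=np.array([0.0, 1.0, 1.0]),
                  y=np.array([0.0, 0.0, 1.0]))
        s = compute_steps(t)
        assert s.phi[1] == pytest.approx(np.pi / 2)

    def test_missing_fix_masks_dependents(self):
        # fixes at t = 0,1,2,4,5 with dt = 1: the step arriving at 4 spans a hole
        t = Track(id="a", times=np.array([0.0, 1.0, 2.0, 4.0, 5.0]),
                  x=np.arange(5.0), y=np.zeros(5))
        s = compute_steps(t)
        at = dict(zip(s.times, zip(s.valid_r, s.valid_phi)))
        assert at[4.0] == (False, False)
        assert at[5.0][0] and not at[5.0][1]  # r valid, phi needs two valid steps
        assert at[2.0] == (True, True)

    def test_zero_length_step_masks_turn(self):
        t = Track(id="a", times=np.arange(4.0), x=np.array([0.0, 1.0, 1.0, 2.0]),
                  y=np.zeros(4))
        s = compute_steps(t)
        assert s.r[1] == 0.0 and s.valid_r[1]
        assert not s.valid_phi[1] and not s.valid_phi[2]  # heading undefined around it

    def test_normalize_by_interval_mode(self):
        t = Track(id="a", times=np.array([0.0, 1.0, 3.0]), x=np.array([0.0, 1.0, 5.0]),
                  y=np.zeros(3))
        s = compute_steps(t, normalize_by_interval=True)
        assert s.valid_r.all()
        assert s.r[1] == pytest.approx(2.0)  # 4 units over 2 intervals

    @given(angle=st.floats(-np.pi, np.pi), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_rotation_invariance(self, angle, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(size=(12, 2)).cumsum(axis=0)
        t = Track(id="a", times=np.arange(12.0), x=xy[:, 0], y=xy[:, 1])
        c, s_ = np.cos(angle), np.sin(angle)
        rot = Track(id="a", times=np.arange(12.0), x=c * xy[:, 0] - s_ * xy[:, 1],
                    y=s_ * xy[:, 0] + c * xy[:, 1])
        a, b = compute_steps(t), compute_steps(rot)
        np.testing.assert_allclose(a.r, b.r, atol=1e-9)
        np.testing.assert_allclose(a.phi[a.valid_phi], b.phi[b.valid_phi], atol=1e-9)

    def test_reflection_negates_angles(self):
        rng = np.random.default_rng(3)
        xy = rng.normal(size=(15, 2)).cumsum(axis=0)
        t = Track(id="a", times=np.arange(15.0), x=xy[:, 0], y=xy[:, 1])
        refl = Track(id="a", times=np.arange(15.0), x=xy[:, 0], y=-xy[:, 1])
        a, b = compute_steps(t), compute_steps(refl)
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)
        np.testing.assert_allclose(a.phi[a.valid_phi], -b.phi[b.valid_phi], atol=1e-12)
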