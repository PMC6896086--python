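"""Persistence ratio, polar coordinates, and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import spherotrack as st
from spherotrack.motility import (
    compare_groups,
    cumulative_displacement,
    direct_distance,
    persistence_ratio,
    polar_coordinates,
    summarize,
    window_ratios,
)
from spherotrack.tracking import Track, TrackSet

# frozen before the build from an independent Monte-Carlo simulator
# (2e5 wrapped-normal walks, direct interval 8, chord interval 2):
# ensemble mean of per-walk persistence ratios at turn_sd = pi
MC_ORACLE_TURNPI = 0.5058
MC_ORACLE_SEM = 0.0002


def straight_track(n=20, step=5.0):
    x = np.arange(n) * step
    return np.column_stack([x, np.zeros(n)])


class TestDirectDistance:
    def test_collinear_track_gives_constant_window_distance(self):
        d = direct_distance(straight_track(), interval=8)
        np.testing.assert_allclose(d, 40.0)
        assert len(d) == 20 - 8

    def test_loop_window_gives_zero(self):
        # returns to start within the window
        theta = np.linspace(0, 2 * np.pi, 9)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        d = direct_distance(xy, interval=8)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_prw_track(self):
        tr = st.simulate_prw_tracks(1, 30, 3.0, 0.7, (5000, 5000), seed=4,
                                    start_positions=[[2500.0, 2500.0]])
        xy = tr.positions[0]
        d = direct_distance(xy, interval=8)
        brute = [np.hypot(*(xy[t + 8] - xy[t])) for t in range(len(xy) - 8)]
        np.testing.assert_allclose(d, brute, rtol=1e-12)

    def test_short_track_gives_empty(self):
        assert len(direct_distance(straight_track(5), interval=8)) == 0


class TestCumulativeDisplacement:
    def test_collinear_track_path_equals_chord(self):
        c = cumulative_displacement(straight_track(), 8, 2)
        np.testing.assert_allclose(c, 40.0)

    def test_stationary_track_gives_zero(self):
        xy = np.zeros((12, 2))
        np.testing.assert_allclose(cumulative_displacement(xy, 8, 2), 0.0)

    def test_matches_brute_force_subsampled_polyline(self):
        tr = st.simulate_prw_tracks(1, 25, 2.0, 1.2, (5000, 5000), seed=6,
                                    start_positions=[[2500.0, 2500.0]])
        xy = tr.positions[0]
        c = cumulative_displacement(xy, 8, 2)
        brute = []
        for t in range(len(xy) - 8):
            pts = xy[t:t + 9:2]
            brute.append(sum(np.hypot(*(pts[i + 1] - pts[i]))
                             for i in range(len(pts) - 1)))
        np.testing.assert_allclose(c, brute, rtol=1e-12)

    def test_incompatible_intervals_rejected(self):
        with pytest.raises(ValueError):
            cumulative_displacement(straight_track(), 8, 3)


class TestPersistenceRatio:
    def test_straight_line_ratio_is_exactly_one(self):
        assert persistence_ratio(straight_track()) == 1.0

    def test_stationary_track_is_undefined(self):
        assert np.isnan(persistence_ratio(np.zeros((15, 2))))

    def test_ratio_never_exceeds_one(self):
        # chord-sampled path >= endpoint chord by the triangle inequality
        for seed in range(20):
            tr = st.simulate_prw_tracks(1, 40, 3.0, 1.0, (5000, 5000),
                                        seed=seed,
                                        start_positions=[[2500.0, 2500.0]])
            r = window_ratios(tr.positions[0])
            assert (r <= 1 + 1e-12).all()

    def test_subsampling_inflation_is_small(self):
        # denominator with cum_interval=1 is the true path; the 2-frame
        # chord sampling may only inflate the ratio slightly
        for seed in range(10):
            tr = st.simulate_prw_tracks(1, 40, 3.0, 0.5, (5000, 5000),
                                        seed=seed,
                                        start_positions=[[2500.0, 2500.0]])
            xy = tr.positions[0]
            r2 = persistence_ratio(xy, 8, 2)
            r1 = persistence_ratio(xy, 8, 1)
            assert r1 <= 1 + 1e-12
            assert r2 - r1 < 0.05

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(angle=hst.floats(0, 2 * np.pi), dx=hst.floats(-100, 100),
           dy=hst.floats(-100, 100), seed=hst.integers(0, 50))
    def test_isometry_invariance(self, angle, dx, dy, seed):
        tr = st.simulate_prw_tracks(1, 20, 2.0, 0.8, (5000, 5000),
                                    seed=seed,
                                    start_positions=[[2500.0, 2500.0]])
        xy = tr.positions[0]
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = xy @ rot.T + [dx, dy]
        assert persistence_ratio(moved) == pytest.approx(
            persistence_ratio(xy), rel=1e-9)

    def test_ensemble_mean_matches_monte_carlo_oracle_at_turnpi(self):
        n = 3000
        tr = st.simulate_prw_tracks(n, 30, 1.0, np.pi, (100000, 100000),
                                    seed=2024,
                                    start_positions=np.full((n, 2), 50000.0))
        ratios = np.array([persistence_ratio(tr.positions[i])
                           for i in range(n)])
        mean = ratios.mean()
        sem = ratios.std(ddof=1) / np.sqrt(n)
        ci = 1.96 * np.sqrt(sem ** 2 + MC_ORACLE_SEM ** 2)
        assert abs(mean - MC_ORACLE_TURNPI) < ci

    def test_mean_ratio_strictly_decreases_with_turning_noise(self):
        means = []
        for turn_sd in (0.0, 0.3, 1.0, np.pi):
            tr = st.simulate_prw_tracks(
                200, 30, 2.0, turn_sd, (100000, 100000), seed=808,
                start_positions=np.full((200, 2), 50000.0))
            means.append(np.mean([persistence_ratio(tr.positions[i])
                                  for i in range(200)]))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestPolarCoordinates:
    def test_rightward_track_is_angle_zero(self):
        ts = TrackSet(tracks=[Track(0, np.arange(10),
                                    straight_track(10, 10 / 9))])
        out = polar_coordinates(ts)
        assert out.loc[0, "angle"] == pytest.approx(0.0)
        assert out.loc[0, "radius"] == pytest.approx(10.0)

    def test_translation_invariance(self):
        xy = straight_track(12)
        a = polar_coordinates(TrackSet(tracks=[Track(0, np.arange(12), xy)]))
        b = polar_coordinates(TrackSet(
            tracks=[Track(0, np.arange(12), xy + [77.0, -31.0])]))
        assert a.equals(b)

    def test_radius_equals_brute_force_net_displacement(self):
        tr = st.simulate_prw_tracks(5, 25, 2.0, 0.6, (5000, 5000), seed=13,
                                    start_positions=np.full((5, 2), 2500.0))
        tracks = [Track(i, np.arange(25), tr.positions[i]) for i in range(5)]
        out = polar_coordinates(TrackSet(tracks=tracks))
        for i in range(5):
            brute = np.hypot(*(tr.positions[i, -1] - tr.positions[i, 0]))
            assert out.loc[i, "radius"] == pytest.approx(brute, rel=1e-12)

    def test_empty_trackset_rejected(self):
        with pytest.raises(ValueError):
            polar_coordinates(TrackSet(tracks=[]))


class TestCompareGroups:
    def test_identical_groups_give_t_zero_p_one(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shifted_groups_match_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, p = compare_groups(a, b)
        # pooled variance = 1, se = sqrt(2/3): t = -10 / sqrt(2/3)
        assert t == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert p < 1e-3

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        t1, p1 = compare_groups(a, b)
        t2, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_tiny_or_nonfinite_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            compare_groups([1.0, np.nan], [2.0, 3.0])


class TestSummarize:
    def test_tracks_shorter_than_window_are_excluded_and_counted(self):
        short = Track(0, np.arange(5), straight_track(5))
        ok = Track(1, np.arange(20), straight_track(20))
        df, excluded = summarize(TrackSet(tracks=[short, ok]))
        assert len(df) == 1
        assert excluded["too_short"] == 1
        assert df.loc[0, "persistence_ratio"] == 1.0
        assert df.loc[0, "n_windows"] == 12

    def test_pooled_mode_emits_one_row_per_window(self):
        ok = Track(1, np.arange(20), straight_track(20))
        df, _ = summarize(TrackSet(tracks=[ok]), mode="pooled")
        assert len(df) == 12
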