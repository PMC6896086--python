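"""Generators: determinism, walk geometry, exact truth areas, cohorts."""

import numpy as np
import pytest
from scipy import stats

import spherotrack as st
from spherotrack.synthetic import (
    SATURATION,
    SyntheticSpheroid,
    make_dispersal_stack,
    simulate_cohort,
)


class TestPRWTracks:
    def test_zero_turning_gives_collinear_equispaced_tracks(self):
        tr = st.simulate_prw_tracks(4, 10, speed=5.0, turn_sd=0.0,
                                    arena=(1000, 1000), seed=7,
                                    start_positions=np.full((4, 2), 500.0))
        for xy in tr.positions:
            steps = np.diff(xy, axis=0)
            np.testing.assert_allclose(np.hypot(*steps.T), 5.0, atol=1e-9)
            # collinear: all steps parallel to the first
            cross = steps[:, 0] * steps[0, 1] - steps[:, 1] * steps[0, 0]
            np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_zero_speed_is_stationary(self):
        tr = st.simulate_prw_tracks(3, 8, speed=0.0, turn_sd=1.0,
                                    arena=(100, 100), seed=1)
        assert np.all(tr.positions == tr.positions[:, :1, :])

    def test_step_length_conservation_without_reflections(self):
        # huge arena, central starts: no wall is ever reached
        tr = st.simulate_prw_tracks(50, 40, speed=3.0, turn_sd=1.0,
                                    arena=(10000, 10000), seed=3,
                                    start_positions=np.full((50, 2), 5000.0))
        steps = np.diff(tr.positions, axis=1)
        np.testing.assert_allclose(np.hypot(steps[..., 0], steps[..., 1]),
                                   3.0, atol=1e-9)

    def test_positions_stay_inside_arena(self):
        tr = st.simulate_prw_tracks(30, 200, speed=10.0, turn_sd=0.1,
                                    arena=(50, 80), seed=5)
        assert tr.positions[..., 0].min() >= 0
        assert tr.positions[..., 0].max() <= 50
        assert tr.positions[..., 1].min() >= 0
        assert tr.positions[..., 1].max() <= 80

    def test_bit_identical_under_same_seed(self):
        a = st.simulate_prw_tracks(5, 20, 2.0, 0.5, (100, 100), seed=11)
        b = st.simulate_prw_tracks(5, 20, 2.0, 0.5, (100, 100), seed=11)
        assert np.array_equal(a.positions, b.positions)
        c = st.simulate_prw_tracks(5, 20, 2.0, 0.5, (100, 100), seed=12)
        assert not np.array_equal(a.positions, c.positions)

    @pytest.mark.parametrize("kwargs", [
        dict(n_cells=0), dict(n_frames=1), dict(speed=-1.0),
        dict(turn_sd=-0.1), dict(arena=(0, 100)),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        base = dict(n_cells=2, n_frames=5, speed=1.0, turn_sd=0.1,
                    arena=(100, 100), seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            st.simulate_prw_tracks(**base)


class TestRenderMovie:
    def test_noiseless_peak_at_true_position(self):
        tr = st.simulate_prw_tracks(1, 3, 2.0, 0.2, (99, 99), seed=2,
                                    start_positions=np.array([[50.0, 50.0]]))
        spec = st.SyntheticMovieSpec(noise_sd=0.0, hot_pixel_rate=0.0,
                                     frame_shape=(100, 100))
        stack = st.render_movie(tr, spec, seed=0)
        for t in range(3):
            y, x = np.unravel_index(stack.frames[t].argmax(), (100, 100))
            assert np.hypot(x - tr.positions[0, t, 0],
                            y - tr.positions[0, t, 1]) <= 1.0

    def test_hot_pixel_count_matches_brute_force_saturation_count(self):
        tr = st.simulate_prw_tracks(1, 5, 0.0, 0.0, (127, 127), seed=2,
                                    start_positions=np.array([[64.0, 64.0]]))
        spec = st.SyntheticMovieSpec(noise_sd=0.0, hot_pixel_rate=0.001,
                                     frame_shape=(128, 128),
                                     peak_intensity=1000.0)
        stack = st.render_movie(tr, spec, seed=9)
        counts = [(frame == SATURATION).sum() for frame in stack.frames]
        # expected ~= 16.4 per 128x128 frame; binomial draws stay well
        # inside a wide window and are reproducible by seed
        assert all(2 <= c <= 50 for c in counts)
        # replay the generator's draws: one binomial + one index draw per frame
        rng = np.random.default_rng(9)
        expected = []
        for _ in range(5):
            n_hot = rng.binomial(128 * 128, 0.001)
            rng.choice(128 * 128, size=n_hot, replace=False)
            expected.append(n_hot)
        assert counts == expected

    def test_identical_seed_gives_identical_stack(self):
        tr = st.simulate_prw_tracks(3, 4, 1.0, 0.3, (63, 63), seed=1)
        spec = st.SyntheticMovieSpec(frame_shape=(64, 64),
                                     hot_pixel_rate=0.002)
        a = st.render_movie(tr, spec, seed=5)
        b = st.render_movie(tr, spec, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_positions_outside_frame_rejected(self):
        tr = st.simulate_prw_tracks(1, 3, 5.0, 0.0, (200, 200), seed=1)
        spec = st.SyntheticMovieSpec(frame_shape=(64, 64))
        with pytest.raises(ValueError, match="outside"):
            st.render_movie(tr, spec, seed=0)


class TestSpheroidPair:
    def test_truth_core_area_equals_brute_force_disk_count(self):
        spec = SyntheticSpheroid(core_radius_t0=20.0, n_dispersed=0)
        img0, img24, truth = st.make_spheroid_pair(spec, seed=0)
        # brute-force rasterized-disk count over the full grid
        side = img0.shape[0]
        c = side / 2.0
        n = sum((x - c) ** 2 + (y - c) ** 2 <= 20.0 ** 2
                for x in range(side) for y in range(side))
        assert truth.sphere_area_t0 == n

    def test_no_dispersed_cells_means_total_equals_core(self):
        spec = SyntheticSpheroid(n_dispersed=0)
        _, _, truth = st.make_spheroid_pair(spec, seed=1)
        assert truth.total_area_t24 == truth.sphere_area_t24

    def test_truth_areas_are_exact_mask_pixel_counts(self):
        spec = SyntheticSpheroid(n_dispersed=8)
        img0, img24, truth = st.make_spheroid_pair(spec, seed=3)
        assert truth.sphere_area_t0 == (img0 > spec.background).sum()
        assert truth.total_area_t24 == (img24 > spec.background).sum()

    def test_same_seed_gives_identical_truth(self):
        spec = SyntheticSpheroid(n_dispersed=10)
        _, _, a = st.make_spheroid_pair(spec, seed=8)
        _, _, b = st.make_spheroid_pair(spec, seed=8)
        assert (a.sphere_area_t0, a.sphere_area_t24, a.total_area_t24) == \
               (b.sphere_area_t0, b.sphere_area_t24, b.total_area_t24)

    def test_halo_smaller_than_core_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpheroid(core_radius_t0=30.0, halo_radius=20.0)

    def test_dispersal_stack_truth_is_monotone(self):
        stack, truth = make_dispersal_stack(6, core_radius=15.0,
                                            halo_growth=4.0, seed=2)
        assert (np.diff(truth) >= 0).all()
        assert stack.n_frames == 6


class TestCohort:
    def test_no_censoring_means_all_events(self):
        spec = st.SyntheticCohortSpec(n_subjects=100, censoring_rate=0.0)
        coh = simulate_cohort(spec, seed=0)
        assert (coh["event"] == 1).all()
        assert (coh["time"] > 0).all()

    def test_censoring_rate_is_calibrated(self):
        spec = st.SyntheticCohortSpec(n_subjects=5000, censoring_rate=0.3)
        coh = simulate_cohort(spec, seed=1)
        assert abs((1 - coh["event"].mean()) - 0.3) < 0.03

    def test_deterministic_given_seed(self):
        spec = st.SyntheticCohortSpec(n_subjects=50)
        a = simulate_cohort(spec, seed=4)
        b = simulate_cohort(spec, seed=4)
        assert a.equals(b)

    def test_null_coefficient_decouples_expression_and_time(self):
        # Kendall correlation ~ 0 within sampling error under the null
        spec = st.SyntheticCohortSpec(n_subjects=2000, coefficient=0.0,
                                      censoring_rate=0.0)
        coh = simulate_cohort(spec, seed=9)
        tau, p = stats.kendalltau(coh["expression"], coh["time"])
        assert abs(tau) < 3 * np.sqrt(2 * (2 * 2000 + 5)
                                      / (9 * 2000 * (2000 - 1)))

    def test_strong_positive_coefficient_shortens_high_stratum_survival(self):
        # high-expression stratum reaches median survival earlier in
        # >= 95% of replicates
        wins = 0
        n_rep = 40
        for i in range(n_rep):
            coh = simulate_cohort(
                st.SyntheticCohortSpec(n_subjects=200, coefficient=1.5),
                seed=300 + i)
            res = st.analyze_cohort(coh)
            wins += (res["curves"]["high"].median
                     < res["curves"]["low"].median)
        assert wins >= 0.95 * n_rep
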