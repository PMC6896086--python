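"""End-to-end validation runs on ground-truthed synthetic data.

Each routine builds its own inputs with the generators, runs the full
pipeline on them, and scores the result against the known truth. They
are used by the test suite and the repository's acceptance script; the
problem sizes are chosen so a full validation pass completes in minutes
on one CPU.
"""

from __future__ import annotations

import hashlib
import os
import tempfile

import numpy as np

from . import synthetic
from .detection import detect_stack
from .motility import persistence_ratio
from .pipeline import MovieConfig, RunConfig, grid_start_positions, run_pipeline
from .survival import analyze_cohort, km_estimate, logrank_test
from .synthetic import SyntheticCohortSpec, SyntheticMovieSpec, SyntheticSpheroid
from .tracking import build_tracks

# Conditions for the rendered tracking movie: 20 cells on a 110-px grid
# (far above the 20-px linking gate), 60 frames, SNR = peak/noise = 75.
# turn_sd = 1 keeps the walks weakly persistent so cells do not drift far
# from their grid cells over the hour of imaging.
TRACKING_MOVIE = MovieConfig(n_cells=20, n_frames=60, speed=2.0,
                             turn_sd=1.0, frame_shape=(420, 560),
                             grid_spacing=110.0, hot_pixel_rate=0.0005)


def _rendered_movie(seed: int, config: MovieConfig = TRACKING_MOVIE):
    starts = grid_start_positions(config.n_cells, config.frame_shape,
                                  config.grid_spacing)
    arena = (config.frame_shape[1] - 1, config.frame_shape[0] - 1)
    tracks = synthetic.simulate_prw_tracks(
        config.n_cells, config.n_frames, config.speed, config.turn_sd,
        arena, seed=seed, start_positions=starts)
    spec = SyntheticMovieSpec(
        psf_sigma=config.psf_sigma, peak_intensity=config.peak_intensity,
        background_level=config.background_level, noise_sd=config.noise_sd,
        hot_pixel_rate=config.hot_pixel_rate,
        frame_shape=config.frame_shape)
    stack = synthetic.render_movie(tracks, spec, seed=seed + 1)
    return tracks, stack


def _match_detection(truth, frame, x, y, max_dist=3.0):
    d = np.hypot(truth.positions[:, frame, 0] - x,
                 truth.positions[:, frame, 1] - y)
    j = int(d.argmin())
    return j if d[j] <= max_dist else -1


def tracking_fidelity(seed: int) -> dict:
    """Render a movie, track it, and score recovered links against truth.

    A predicted link is correct when its two detections map to the same
    true cell; any other link is false. The ground truth has
    n_cells * (n_frames - 1) links.
    """
    truth, stack = _rendered_movie(seed)
    det = detect_stack(stack)
    ts = build_tracks(det)
    correct = false = 0
    for track in ts.tracks:
        for a in range(len(track) - 1):
            ia = _match_detection(truth, track.frames[a],
                                  track.xy[a, 0], track.xy[a, 1])
            ib = _match_detection(truth, track.frames[a + 1],
                                  track.xy[a + 1, 0], track.xy[a + 1, 1])
            if ia >= 0 and ia == ib:
                correct += 1
            else:
                false += 1
    n_true_links = truth.n_cells * (truth.n_frames - 1)
    return {
        "n_true_links": n_true_links,
        "n_correct_links": correct,
        "n_false_links": false,
        "recall": correct / n_true_links,
        "n_tracks": len(ts),
        "n_detections": len(det),
    }


def persistence_recovery(seed: int) -> dict:
    """Compare pipeline persistence ratios with ground-truth-track ratios.

    Tracks recovered from the rendered movie are matched to true cells by
    their start position; the relative error of the per-track ratio is
    reported. Also simulates a free-space turn_sd = pi ensemble and
    reports its mean ratio for comparison against an independent
    Monte-Carlo value.
    """
    truth, stack = _rendered_movie(seed)
    det = detect_stack(stack)
    ts = build_tracks(det, min_track_length=truth.n_frames)
    rel_errors = []
    for track in ts.tracks:
        cell = _match_detection(truth, track.frames[0],
                                track.xy[0, 0], track.xy[0, 1])
        if cell < 0:
            continue
        est = persistence_ratio(track.xy)
        ref = persistence_ratio(truth.positions[cell])
        rel_errors.append(abs(est - ref) / ref)
    # free-space ensemble at turn_sd = pi (arena large enough that no
    # walk ever reaches a wall)
    n = 3000
    ens = synthetic.simulate_prw_tracks(
        n, 30, 1.0, np.pi, (100000, 100000), seed=seed + 7,
        start_positions=np.full((n, 2), 50000.0))
    ratios = np.array([persistence_ratio(ens.positions[i])
                       for i in range(n)])
    return {
        "n_tracks_scored": len(rel_errors),
        "max_rel_error": float(np.max(rel_errors)),
        "mean_rel_error": float(np.mean(rel_errors)),
        "turnpi_ensemble_mean": float(ratios.mean()),
        "turnpi_ensemble_sem": float(ratios.std(ddof=1) / np.sqrt(n)),
    }


def persistence_limits(seed: int) -> dict:
    """Exact straight-line limit and monotone decay with turning noise."""
    straight = np.column_stack([np.arange(20) * 5.0, np.zeros(20)])
    ladder = []
    for turn_sd in (0.0, 0.3, 1.0, np.pi):
        tr = synthetic.simulate_prw_tracks(
            200, 30, 2.0, turn_sd, (100000, 100000), seed=seed,
            start_positions=np.full((200, 2), 50000.0))
        ladder.append(float(np.mean([persistence_ratio(tr.positions[i])
                                     for i in range(200)])))
    return {
        "straight_line_ratio": float(persistence_ratio(straight)),
        "ladder_means": ladder,
        "strictly_decreasing": all(a > b for a, b in zip(ladder, ladder[1:])),
    }


def assignment_optimality(seed: int, n_instances: int = 1000) -> dict:
    """link_frames vs exhaustive enumeration on random small instances."""
    import itertools

    from .tracking import link_frames

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n, m = rng.integers(0, 7, size=2)
        a = rng.uniform(0, 40, (int(n), 2))
        b = rng.uniform(0, 40, (int(m), 2))
        gate = float(rng.uniform(5, 30))
        pairs = link_frames(a, b, gate) if n and m else []
        cost = sum(float(np.sum((a[i] - b[j]) ** 2)) for i, j in pairs)
        # exhaustive lexicographic optimum
        g2 = gate ** 2
        best_k, best_cost = 0, 0.0
        for k in range(min(int(n), int(m)), -1, -1):
            found = None
            for rows in itertools.combinations(range(int(n)), k):
                for cols in itertools.permutations(range(int(m)), k):
                    cs = [float(np.sum((a[r] - b[q]) ** 2))
                          for r, q in zip(rows, cols)]
                    if all(x <= g2 for x in cs):
                        tot = sum(cs)
                        if found is None or tot < found:
                            found = tot
            if found is not None:
                best_k, best_cost = k, found
                break
        agree += (len(pairs) == best_k
                  and abs(cost - best_cost) <= 1e-9 * max(1.0, best_cost))
    return {"n_instances": n_instances, "n_agree": agree,
            "fraction_agree": agree / n_instances}


def dispersal_exactness(seed: int, n_pairs: int = 5) -> dict:
    """Segmented areas vs generator truth, plus 2x-rescale drift."""
    from skimage.transform import rescale

    from .dispersal import measure_pair

    abs_errors = []
    drifts = []
    for k in range(n_pairs):
        img0, img24, truth = synthetic.make_spheroid_pair(
            SyntheticSpheroid(n_dispersed=12), seed=seed + k)
        meas = measure_pair(img0, img24)
        abs_errors.append(abs(meas.dispersal_area - truth.dispersal_area))
        up0 = rescale(img0.astype(float), 2, order=1, preserve_range=True)
        up24 = rescale(img24.astype(float), 2, order=1, preserve_range=True)
        meas2 = measure_pair(up0, up24, close_radius=10)
        drifts.append(abs(meas2.dispersal_area - meas.dispersal_area)
                      / meas.dispersal_area)
    return {
        "n_pairs": n_pairs,
        "max_abs_error": float(np.max(abs_errors)),
        "max_rescale_drift": float(np.max(drifts)),
    }


def survival_correctness(seed: int, n_null: int = 1000,
                         n_power: int = 400) -> dict:
    """Oracle fixtures, null calibration, and power ordering."""
    # hand product-limit fixture: times (2,4,4,6), events (1,1,1,0)
    curve = km_estimate([2.0, 4.0, 4.0, 6.0], [1, 1, 1, 0])
    km_err = float(np.max(np.abs(curve.survival - np.array([0.75, 0.25]))))

    # identical strata: chi-square exactly 0
    chi0, _ = logrank_test([1.0, 2.0, 3.0] * 2, [1, 1, 0] * 2,
                           ["a"] * 3 + ["b"] * 3)

    rejections = 0
    for i in range(n_null):
        coh = synthetic.simulate_cohort(
            SyntheticCohortSpec(n_subjects=200, coefficient=0.0),
            seed=seed + 10_000 + i)
        rejections += analyze_cohort(coh)["p_value"] < 0.05
    type1 = rejections / n_null

    powers = []
    for coef in (0.0, 0.3, 0.7, 1.2):
        rej = 0
        for i in range(n_power):
            coh = synthetic.simulate_cohort(
                SyntheticCohortSpec(n_subjects=100, coefficient=coef),
                seed=seed + 50_000 + i)
            rej += analyze_cohort(coh)["p_value"] < 0.05
        powers.append(rej / n_power)

    return {
        "km_fixture_max_abs_error": km_err,
        "identical_strata_chi_square": float(chi0),
        "type1_rate": type1,
        "n_null": n_null,
        "power_by_coefficient": powers,
        "power_non_decreasing": all(b >= a for a, b in
                                    zip(powers, powers[1:])),
    }


def determinism_check(seed: int) -> dict:
    """Run the full pipeline twice under one seed; hash every output."""
    cfg = RunConfig.from_yaml(f"""
seed: {seed}
movie: {{n_cells: 6, n_frames: 20, frame_shape: [160, 240], grid_spacing: 80}}
cohort: {{n_subjects: 60}}
""")

    def hashes(outdir):
        out = {}
        for name in sorted(os.listdir(outdir)):
            if name == "manifest.json" or not name.endswith(
                    (".csv", ".json", ".tif")):
                continue
            with open(os.path.join(outdir, name), "rb") as fh:
                out[name] = hashlib.sha256(fh.read()).hexdigest()
        return out

    with tempfile.TemporaryDirectory() as tmp:
        run_pipeline(cfg, os.path.join(tmp, "a"))
        run_pipeline(cfg, os.path.join(tmp, "b"))
        ha = hashes(os.path.join(tmp, "a"))
        hb = hashes(os.path.join(tmp, "b"))
    return {"n_outputs": len(ha), "identical": ha == hb and len(ha) > 0}
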