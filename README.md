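# spherotrack

Quantitative analysis of glioblastoma-style tumor-spheroid dispersal and
single-cell motility, plus expression-stratified patient-survival
analysis — implemented as one reusable, seed-reproducible pipeline and
exercised end-to-end on synthetic data with known ground truth.

## What it measures

**Spheroid dispersal.** A tumor spheroid attached to a substrate sheds
motile cells that spread outward over 24 h. From a t0/t24 image pair the
pipeline segments the remaining spheroid body (core) and the total
occupied footprint and computes the dispersal index

```
dispersal_area = (total_area(24 h) − sphere_area(24 h)) / sphere_area(0 h)
```

on exact pixel counts. For live imaging it reports the per-frame
footprint area relative to frame 0.

**Single-cell motility.** Time-lapse movies are processed as
detection → linking → persistence:

- *Detection*: saturated point defects are median-repaired, the frame is
  smoothed with a Gaussian of σ ≥ 3 px, thresholded (Otsu by default),
  and each connected component yields an intensity-weighted centroid.
- *Linking*: consecutive frames are associated by the globally optimal
  one-to-one assignment minimizing total squared displacement, with a
  hard gate on per-link displacement (default 20 px). No gap closing.
- *Persistence*: for each track, sliding 8-frame windows give a direct
  (chord) distance `D` and a cumulative path `C` summed over 2-frame
  chords; the persistence ratio is the per-track mean of `D/C`. Ratios
  near 1 mean linear movement, low ratios mean random migration.
  Trajectories are also exported as origin-aligned polar plots, and
  groups are compared with the classical pooled-variance two-tailed
  Student's t-test.

**Survival analysis.** For a cohort with one expression value per
subject: `log2(x + 1)` transform, z-normalization within the cohort
(population SD), mean-split into high/low strata, Kaplan–Meier
product-limit curves per stratum

```
S(t) = Π_{t_i ≤ t} (1 − d_i / n_i)
```

and the two-sample log-rank test, `χ² = (ΣO − ΣE)² / ΣV` with
hypergeometric expectation and variance at each event time. The
estimator and test are implemented from first principles; `lifelines`
is used only as an independent cross-check in the test suite.

**Synthetic ground truth.** A generator module produces (a) persistent
random walks — heading increments η ~ N(0, turn_sd²), fixed step length,
reflecting boundaries — rendered as Gaussian-spot movies with read noise
and saturated hot pixels; (b) spheroid core + dispersed-halo image pairs
whose truth areas are exact mask pixel counts; (c) survival cohorts with
exponential event times whose hazard is log-linear in the standardized
expression value. Every generator is bit-reproducible from an explicit
seed.

## Worked example

```python
import numpy as np
import spherotrack as st

# 12 cells, 40 frames, persistent walks rendered at SNR 75
starts = np.array([[40.0 + 80 * (i % 4), 40.0 + 80 * (i // 4)]
                   for i in range(12)])
tracks = st.simulate_prw_tracks(n_cells=12, n_frames=40, speed=2.0,
                                turn_sd=0.4, arena=(319, 319), seed=7,
                                start_positions=starts)
movie = st.render_movie(tracks, st.SyntheticMovieSpec(
    frame_shape=(320, 320), hot_pixel_rate=0.0005), seed=8)

detections = st.detect_stack(movie)            # 480 detections
track_set = st.build_tracks(detections)        # 12 tracks
summary, _ = st.summarize(track_set)
print(summary.persistence_ratio.mean())        # 0.930

img0, img24, truth = st.make_spheroid_pair(
    st.SyntheticSpheroid(n_dispersed=12), seed=9)
m = st.measure_pair(img0, img24)
print(m.dispersal_area)                        # 0.2665 (truth: 0.2665)

cohort = st.simulate_cohort(
    st.SyntheticCohortSpec(n_subjects=200, coefficient=0.8), seed=10)
res = st.analyze_cohort(cohort)
print(res["chi_square"], res["p_value"])       # 49.915, 1.61e-12
```

The 480 detections are the 12 cells recovered in every one of the 40
frames (no spurious detections despite the hot pixels); the mean
persistence ratio 0.93 reflects the low turning noise (turn_sd = 0.4).
The dispersal index from automated segmentation equals the value from
the generator's truth areas exactly. In the cohort, a log-hazard of 0.8
per expression SD makes the high-expression stratum die much earlier
(median 255 vs 859 days), which the log-rank test flags at p ≈ 1.6e-12.

The same workflow is available from the shell:

```bash
spherotrack demo --seed 0 --outdir demo_run
spherotrack synth cohort --n-subjects 200 --coefficient 0.8 --seed 10 --out cohort.csv
spherotrack survival cohort.csv --out-prefix surv
```

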