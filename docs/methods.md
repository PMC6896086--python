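# Methods

This note records the models, conventions, and numerical choices behind
spherotrack, and what the synthetic-data experiments do and do not show.

## Synthetic data model

**Persistent random walk (PRW).** Cell motion is simulated as a
fixed-step walk: at each frame the heading receives an independent
normal increment η ~ N(0, turn_sd²) and the position advances by exactly
`speed` pixels along the new heading. `turn_sd` (radians/frame) is the
single persistence knob: 0 gives straight lines, π gives nearly
isotropic re-orientation each frame. The walk was chosen because its
direct-to-cumulative distance ratio is tunable across the full (0, 1]
range; it is not fitted to any particular cell line. Boundaries reflect
(position mirrored, heading component flipped) rather than absorb, so
every simulated cell yields a full-length truth track for the tracker to
recover. Reflected steps preserve path length but not displacement;
free-space statistics are therefore collected in arenas large enough
that no wall is reached.

**Imaging model.** Cells render as isotropic Gaussian spots of scale
`psf_sigma` (default 2 px) and amplitude `peak_intensity` over a uniform
background, with additive Gaussian read noise and a binomial number of
saturated single-pixel hot spots per frame. Defaults
(peak 30000, background 800, noise 400 on a 16-bit scale) give a
peak-signal-to-noise ratio of 75 and — deliberately — a per-cell
integrated flux (peak·2πσ² ≈ 7.5e5) an order of magnitude above the
flux of a saturated defect (65535), which is the regime in which
filter-based defect suppression is physically sensible. The model omits
cell morphology, intensity variation between cells, division, death,
photobleaching, drift, and out-of-focus light; passing tests therefore
demonstrate algorithmic correctness under the stated model, not
performance on arbitrary real microscopy.

**Spheroid images.** A centered disk (core) plus non-overlapping small
disks (dispersed cells) in an annulus, rendered as two-level grayscale.
Truth areas are the exact pixel counts of the rendered masks, so
segmentation can be scored without tolerance. Blob placement keeps a
16-px clearance between the core edge and any blob edge — larger than
twice the default morphological closing radius — so that closing can
never fuse a dispersed cell into the core.

**Survival cohorts.** Each subject's raw expression is lognormal
(base 2); its standardized log2 score z sets an exponential event-time
hazard λ = λ₀·exp(β·z), with β the log-hazard per expression SD
(β = 0 decouples expression from survival). Censoring is independent
uniform C ~ U(0, u); u is solved numerically so the expected censored
fraction at the baseline hazard equals the requested `censoring_rate`
(the closed form is P(C < T) = (1 − e^{−λ₀u})/(λ₀u)). Defaults: 200
subjects, λ₀ = 1/500 per day, 30 % censoring — a plausible shape for a
several-hundred-patient brain-tumor cohort followed for a few years.

## Detection

- "Lower bound of 3 pixels" on the Gaussian denoiser is enforced on the
  *sigma* of the filter (kernel truncation at 4σ). The alternative
  reading — a 3-px kernel extent — would barely attenuate a point
  defect and is available only through an explicit
  `allow_small_sigma=True` opt-out.
- Saturated pixels are repaired with a 3×3 median before smoothing.
  Isolated defects are already removed by the Gaussian alone, but two
  coincident defects retain enough flux to survive thresholding at
  realistic defect rates; since hot pixels read out at full scale
  regardless of the scene, exact-saturation repair is a safe and
  deterministic criterion. Padding is mirror-mode, because
  nearest/replicate padding multiplies the flux of a defect sitting on
  the frame border.
- Threshold default is Otsu with a guard for blank frames: if the
  foreground/background mean separation is under 3 background SDs the
  frame is declared empty instead of splitting pure noise. An absolute
  threshold can be supplied instead.
- `min_area` default 4 px discards sub-cellular residue. Centroids are
  intensity-weighted means over each component; coordinates are 0-based
  pixel centers, x rightward, y downward, everywhere in the package.

## Tracking

Frame-to-frame association minimizes total squared displacement subject
to a hard gate (default 20 px, set per dataset). "Minimal" is read
lexicographically: first maximize the number of within-gate links, then
minimize the summed squared displacement — otherwise the empty pairing
would be vacuously optimal. The implementation pads the cost matrix
with per-detection dummy nodes (unmatched cost larger than any feasible
total) and solves the square assignment problem exactly
(`scipy.optimize.linear_sum_assignment`); the test suite checks it
against exhaustive enumeration. Equal-cost optima are resolved
deterministically by the solver. There is no gap closing and no
merge/split handling: a missed detection ends a track and starts a new
one. `min_track_length` defaults to 9 = direct-distance interval + 1,
so every retained track yields at least one persistence window.

## Persistence statistics

Direct distance uses 8-frame windows (stride 1); the cumulative path in
the *same* window is the sum of 2-frame chords. The coarse denominator
sampling follows the anti-jitter rationale: summing every single-frame
step would inflate the path with centroid noise and bias persistence
downward. Because the 2-frame polyline still majorizes the 8-frame
chord, the ratio stays in [0, 1] by the triangle inequality; relative
to a single-frame denominator the inflation is small (< 0.05 on the
fixture grid, verified by test). Windows with zero cumulative
displacement are excluded and counted; tracks shorter than 9 frames are
excluded, not padded. Per-cell aggregation is the mean over windows; a
pooled-per-window mode exists because either convention is defensible.
Both the per-window mean direct distance and the whole-track net
displacement are reported. Physical units (µm, minutes) are applied
only at reporting time.

An independent Monte-Carlo simulation (2×10⁵ walks, written before the
pipeline and kept outside it) fixed the expected ensemble mean
persistence ratio at turn_sd = π to 0.5058 (SEM 2×10⁻⁴); the pipeline
ensemble is compared against that value under a combined 95 % CI.

## Dispersal

The index (total_t24 − sphere_t24)/sphere_t0 is computed on integer
pixel counts with no intermediate rounding. Segmentation: threshold
(Otsu default), total footprint = union of above-threshold components;
core = largest connected component after morphological closing
(disk radius 5, configurable), intersected with the footprint so
core ⊆ footprint. A polarity flag handles dark-on-bright contrast, and
pre-drawn binary masks can be imported to mirror a manual-outline
workflow. The live-imaging time course divides each frame's footprint
area by the frame-0 footprint, so it starts at 1 by construction.

## Survival

Kaplan–Meier and the log-rank test are implemented directly. Recorded
conventions (all configurable where noted): population SD (divisor n)
for z-normalization; log2 pseudocount 1; mean-split ties assigned to
"low"; at a tied event/censoring time the censored subject remains in
the risk set (censoring processed after events); tied events use the
hypergeometric variance with the (n−d)/(n−1) correction. A reference
implementation (lifelines) reproduces curves and statistics to 1e-9 on
random fixtures in the test suite.

## Pipeline and reproducibility

One YAML config with per-stage sections drives the run; unknown keys
and invalid values are rejected with the offending field names. All
randomness flows from the single config seed (stage seeds are fixed
offsets of it); reruns are byte-identical for every CSV/JSON/TIFF
output, and figures are written without timestamps. Each run writes a
manifest with the package version, seed, full parameter echo, and
record counts per output.

## Validation problem sizes

The bundled validation suite uses a 20-cell, 60-frame movie at SNR 75
with 110-px grid spacing (tracking and persistence recovery), 3000
free-space walks for the turn_sd = π ensemble, 200-walk ensembles per
turning-noise level, 1000 random linking instances with ≤ 6 detections
per frame, 5 spheroid pairs, 1000 null cohorts of 200 subjects for the
type-I check and 400 cohorts of 100 subjects per hazard coefficient for
the power ladder. These sizes keep a full pass under a minute while
leaving the statistical checks well-powered.

## Known limitations

- Detection assumes blob-like, well-separated cells; touching cells are
  not split and merged detections end tracks.
- The tracker has no motion model or appearance features; it will swap
  identities when cells pass within a step-length of each other.
- The PRW has constant speed; speed fluctuations of real cells widen
  the persistence-ratio distribution beyond what the ensemble tests
  exercise.
- The survival module handles exactly two strata and a single gene at a
  time; multivariate models are out of scope.
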