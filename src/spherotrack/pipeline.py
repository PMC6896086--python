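"""End-to-end orchestration: config, staging, manifests, reproducibility.

A run is described by one YAML config with per-stage sections; unknown
keys are rejected at load time. Every run writes a manifest (parameter
echo, package version, seed, outputs with record counts) sufficient to
reproduce the deterministic stages byte-for-byte.
"""

from __future__ import annotations

import json
import os
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from . import dispersal as dispersal_mod
from . import io as io_mod
from . import motility as motility_mod
from . import survival as survival_mod
from . import synthetic
from .detection import detect_stack
from .tracking import build_tracks


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MovieConfig(_Strict):
    n_cells: int = 20
    n_frames: int = 60
    speed: float = 2.0
    turn_sd: float = 0.3
    psf_sigma: float = 2.0
    peak_intensity: float = 30000.0
    background_level: float = 800.0
    noise_sd: float = 400.0
    hot_pixel_rate: float = 0.0005
    frame_shape: tuple[int, int] = (400, 480)
    grid_spacing: float = 80.0


class DetectionConfig(_Strict):
    sigma: float = Field(3.0, gt=0)
    threshold: float | Literal["otsu"] = "otsu"
    min_area: int = Field(4, ge=1)


class TrackingConfig(_Strict):
    gate_radius: float = Field(20.0, gt=0)
    min_track_length: int = Field(9, ge=2)


class MotilityConfig(_Strict):
    direct_interval: int = Field(8, ge=1)
    cum_interval: int = Field(2, ge=1)
    mode: Literal["per_cell", "pooled"] = "per_cell"


class SpheroidConfig(_Strict):
    core_radius_t0: float = 20.0
    core_radius_t24: float = 18.0
    n_dispersed: int = 12
    halo_radius: float = 60.0
    threshold: float | Literal["otsu"] = "otsu"
    close_radius: int = Field(5, ge=0)


class CohortConfig(_Strict):
    n_subjects: int = Field(200, ge=2)
    coefficient: float = 0.7
    baseline_hazard: float = Field(1.0 / 500.0, gt=0)
    censoring_rate: float = Field(0.3, ge=0, lt=1)


class CalibrationConfig(_Strict):
    pixel_size: float | None = None      # µm per px
    frame_interval: float | None = None  # minutes per frame


class RunConfig(_Strict):
    """Parameters for every pipeline stage plus seed and calibration."""

    seed: int = 0
    stages: list[Literal["tracking", "spheroid", "cohort"]] = \
        Field(default_factory=lambda: ["tracking", "spheroid", "cohort"])
    movie: MovieConfig = Field(default_factory=MovieConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    tracking: TrackingConfig = Field(default_factory=TrackingConfig)
    motility: MotilityConfig = Field(default_factory=MotilityConfig)
    spheroid: SpheroidConfig = Field(default_factory=SpheroidConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        try:
            return cls.model_validate(data)
        except ValidationError as err:
            bad = sorted({".".join(str(p) for p in e["loc"])
                          for e in err.errors()})
            raise ValueError(
                f"invalid config, offending keys: {bad}") from err


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_yaml(fh.read())


def grid_start_positions(n_cells: int, frame_shape: tuple[int, int],
                         spacing: float) -> np.ndarray:
    """Well-separated lattice starts centered in the frame."""
    h, w = frame_shape
    n_cols = max(int((w - spacing) // spacing) + 1, 1)
    xs, ys = [], []
    for i in range(n_cells):
        r, c = divmod(i, n_cols)
        xs.append(spacing / 2 + c * spacing + (w - n_cols * spacing) / 2)
        ys.append(spacing / 2 + r * spacing)
    pos = np.column_stack([xs, ys])
    if (pos[:, 0] > w - 1).any() or (pos[:, 1] > h - 1).any():
        raise ValueError("frame_shape too small for n_cells at this spacing")
    return pos


def run_pipeline(config: RunConfig, outdir: str) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "outputs": {},
    }

    def record(name: str, path: str, n: int):
        manifest["outputs"][name] = {"path": os.path.basename(path),
                                     "n_records": int(n)}

    if "tracking" in config.stages:
        mc = config.movie
        arena = (mc.frame_shape[1] - 1, mc.frame_shape[0] - 1)
        starts = grid_start_positions(mc.n_cells, mc.frame_shape,
                                      mc.grid_spacing)
        tracks = synthetic.simulate_prw_tracks(
            mc.n_cells, mc.n_frames, mc.speed, mc.turn_sd, arena,
            seed=config.seed, start_positions=starts)
        spec = synthetic.SyntheticMovieSpec(
            psf_sigma=mc.psf_sigma, peak_intensity=mc.peak_intensity,
            background_level=mc.background_level, noise_sd=mc.noise_sd,
            hot_pixel_rate=mc.hot_pixel_rate, frame_shape=mc.frame_shape)
        stack = synthetic.render_movie(tracks, spec, seed=config.seed + 1)

        movie_path = os.path.join(outdir, "movie.tif")
        io_mod.write_stack(movie_path, stack)
        truth_path = os.path.join(outdir, "truth_tracks.csv")
        truth_df = tracks.to_dataframe()
        truth_df.to_csv(truth_path, index=False)
        record("movie", movie_path, stack.n_frames)
        record("truth_tracks", truth_path, len(truth_df))

        det = detect_stack(stack, sigma=config.detection.sigma,
                           threshold=config.detection.threshold,
                           min_area=config.detection.min_area)
        det_path = os.path.join(outdir, "detections.csv")
        io_mod.write_detections(det_path, det)
        record("detections", det_path, len(det))

        ts = build_tracks(det, gate_radius=config.tracking.gate_radius,
                          min_track_length=config.tracking.min_track_length)
        trk_path = os.path.join(outdir, "tracks.csv")
        io_mod.write_tracks(trk_path, ts)
        record("tracks", trk_path, len(ts))

        summary, excluded = motility_mod.summarize(
            ts, config.motility.direct_interval, config.motility.cum_interval,
            mode=config.motility.mode)
        if config.calibration.pixel_size:
            summary["mean_direct_distance_um"] = \
                summary["mean_direct_distance"] * config.calibration.pixel_size
        sum_path = os.path.join(outdir, "motility_summary.csv")
        summary.to_csv(sum_path, index=False)
        record("motility_summary", sum_path, len(summary))
        manifest["motility_excluded"] = excluded

        polar = motility_mod.polar_coordinates(ts)
        polar_path = os.path.join(outdir, "polar.csv")
        polar.to_csv(polar_path, index=False)
        record("polar", polar_path, len(polar))
        motility_mod.save_polar_plot(ts, os.path.join(outdir, "polar.svg"))

    if "spheroid" in config.stages:
        sc = config.spheroid
        spec = synthetic.SyntheticSpheroid(
            core_radius_t0=sc.core_radius_t0,
            core_radius_t24=sc.core_radius_t24,
            n_dispersed=sc.n_dispersed, halo_radius=sc.halo_radius)
        img0, img24, truth = synthetic.make_spheroid_pair(
            spec, seed=config.seed + 2)
        meas = dispersal_mod.measure_pair(img0, img24,
                                          threshold=sc.threshold,
                                          close_radius=sc.close_radius)
        import pandas as pd
        df = pd.DataFrame([{
            "sphere_area_t0": meas.sphere_area_t0,
            "sphere_area_t24": meas.sphere_area_t24,
            "total_area_t24": meas.total_area_t24,
            "dispersal_area": meas.dispersal_area,
            "truth_dispersal_area": truth.dispersal_area,
        }])
        sp_path = os.path.join(outdir, "spheroid_measurement.csv")
        df.to_csv(sp_path, index=False)
        record("spheroid_measurement", sp_path, len(df))

    if "cohort" in config.stages:
        cc = config.cohort
        spec = synthetic.SyntheticCohortSpec(
            n_subjects=cc.n_subjects, coefficient=cc.coefficient,
            baseline_hazard=cc.baseline_hazard,
            censoring_rate=cc.censoring_rate)
        cohort = synthetic.simulate_cohort(spec, seed=config.seed + 3)
        result = survival_mod.analyze_cohort(cohort)
        coh_path = os.path.join(outdir, "cohort.csv")
        result["cohort"].to_csv(coh_path, index=False)
        record("cohort", coh_path, len(cohort))
        for label, curve in result["curves"].items():
            km_path = os.path.join(outdir, f"km_{label}.csv")
            survival_mod.km_table(curve).to_csv(km_path, index=False)
            record(f"km_{label}", km_path, len(curve.event_times))
        survival_mod.save_km_plot(result["curves"],
                                  os.path.join(outdir, "km.svg"))
        report = {"chi_square": result["chi_square"],
                  "p_value": result["p_value"]}
        rep_path = os.path.join(outdir, "logrank.json")
        with open(rep_path, "w") as fh:
            json.dump(report, fh, indent=2)
        record("logrank", rep_path, 1)
        manifest["logrank"] = report

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
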