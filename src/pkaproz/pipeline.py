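"""End-to-end pipeline: simulate, render, analyze, score.

A run is described by a :class:`RunConfig` (YAML on disk), executed stage
by stage — model curves, synthetic movie rendering, image analysis,
scoring against the generator's ground truth — with per-stage error
capture so one failed stage does not abort the independent ones.  The
archived config plus the seed make a run exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gradient as gradient_mod
from . import imaging, prozone, synthetic, translocation

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "analyze_fret_movie",
    "analyze_cytoplasm",
    "track_chip_nuclei",
    "analyze_chip_profiles",
]

log = logging.getLogger(__name__)

_ANALYSIS_DEFAULTS = {
    "segmentation_threshold": 250.0,
    "nuclear_threshold": 700.0,
    "min_expression": 150.0,
    "erosion_depth": 20,
}


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one pipeline run."""

    scenario: dict
    outdir: str = "runs/out"
    seed: int = 0
    pixel_size: float = imaging.DEFAULT_PIXEL_SIZE_UM
    analysis: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.analysis) - set(_ANALYSIS_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown analysis keys: {sorted(unknown)}; "
                             f"valid: {sorted(_ANALYSIS_DEFAULTS)}")

    @property
    def analysis_params(self) -> dict:
        return {**_ANALYSIS_DEFAULTS, **self.analysis}

    def to_scenario(self) -> synthetic.Scenario:
        return synthetic.Scenario(seed=self.seed, **self.scenario)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"valid: {sorted(valid)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))


@dataclass
class RunReport:
    """Per-stage outcomes, recovery metrics and pass/fail flags."""

    config: dict
    stages: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    passes: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages.values())

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "stages": self.stages,
            "metrics": self.metrics, "passes": self.passes,
        }, indent=1, default=synthetic._jsonable))


# ---------------------------------------------------------------------------
# analysis entry points (thin compositions of the imaging module)

def analyze_fret_movie(movie: dict, dark: float, seg_threshold: float,
                       min_expression: float = 0.0,
                       expr_channel: str = "YFP",
                       cfp_channel: str = "CFP") -> dict:
    """Per-cell FRET ratio time series from a dish-type movie.

    Cells are segmented once in the expression channel at t = 0 (the
    synthetic dishes are drift-free), the dark-corrected emission ratio is
    computed per frame, and each cell's mean ratio collected.  Returns the
    masks, the (cells x T) ratio array, and each cell's maximal percent
    ratio increase over its t = 0 value.
    """
    expr0 = imaging.ImageFrame(movie[expr_channel][0], channel=expr_channel,
                               dark_frame=dark)
    masks = imaging.threshold_segment(expr0, seg_threshold)
    if not masks:
        raise ValueError(f"no cells found above threshold {seg_threshold}")
    T = movie["FRET_em"].shape[0]
    series = np.full((len(masks), T), np.nan)
    excluded = {}
    for k in range(T):
        fret = imaging.ImageFrame(movie["FRET_em"][k], channel="FRET_em",
                                  dark_frame=dark)
        cfp = imaging.ImageFrame(movie[cfp_channel][k], channel=cfp_channel,
                                 dark_frame=dark)
        rmap = imaging.fret_ratio_map(fret, cfp, masks)
        for m in masks:
            res = imaging.cell_mean_ratio(rmap, m, expr0, min_expression)
            if res.excluded:
                excluded[m.cell_id] = res.reason
            else:
                series[m.cell_id, k] = res.value
    keep = [m.cell_id for m in masks if m.cell_id not in excluded]
    kept = series[keep]
    max_increase_pct = (np.nanmax(kept, axis=1) - kept[:, 0]) / kept[:, 0] * 100
    return {"masks": masks, "ratio_series": series, "kept_ids": keep,
            "max_increase_pct": max_increase_pct, "excluded": excluded}


def analyze_cytoplasm(movie: dict, dark: float, seg_threshold: float,
                      erosion_depth: int = 20,
                      track_channel: str = "mCherry") -> dict:
    """Normalized cytoplasmic intensity per cell from a translocation movie."""
    expr0 = imaging.ImageFrame(movie["YFP"][0], channel="YFP",
                               dark_frame=dark)
    masks = imaging.threshold_segment(expr0, seg_threshold)
    frames = movie[track_channel] - dark
    frames = np.maximum(frames, 0.0)
    results = {}
    for m in masks:
        stack = np.broadcast_to(m.mask, frames.shape)
        results[m.cell_id] = imaging.cytoplasmic_intensity_series(
            frames, stack, erosion_depth)
    return {"masks": masks, "series": results}


def track_chip_nuclei(movie: dict, n_channels: int, nuclear_threshold: float,
                      dark: float, t_min=None,
                      pixel_size: float = imaging.DEFAULT_PIXEL_SIZE_UM
                      ) -> list[imaging.NuclearTrack]:
    """Nuclear displacement per cross-channel from the marker channel."""
    cfp = movie["CFP"]
    width = cfp.shape[2] // n_channels
    tracks = []
    for i in range(n_channels):
        crop = cfp[:, :, i * width:(i + 1) * width] - dark
        tracks.append(imaging.nuclear_displacement(
            np.maximum(crop, 0.0), nuclear_threshold, t=t_min,
            pixel_size=pixel_size, cell_id=i))
    return tracks


def analyze_chip_profiles(movie: dict, dark: float, seg_threshold: float,
                          frame: int = -1, n_bins: int = 20) -> list:
    """20-bin intracellular ratio profile per cell at one chip frame."""
    T = movie["FRET_em"].shape[0]
    k = frame % T
    expr = imaging.ImageFrame(movie["YFP"][k], channel="YFP",
                              dark_frame=dark)
    masks = imaging.threshold_segment(expr, seg_threshold)
    fret = imaging.ImageFrame(movie["FRET_em"][k], dark_frame=dark)
    donor = imaging.ImageFrame(movie["CFP_donor"][k], dark_frame=dark)
    rmap = imaging.fret_ratio_map(fret, donor, masks)
    return [(m, imaging.bin_profile(rmap, m, axis="row", n_bins=n_bins))
            for m in masks]


# ---------------------------------------------------------------------------
# orchestration

def _stage(report: RunReport, name: str, fn):
    t0 = time.time()
    try:
        out = fn()
        report.stages[name] = {"status": "ok",
                               "elapsed_s": round(time.time() - t0, 2)}
        return out
    except Exception as exc:  # stage isolation by design
        log.error("stage %s failed: %s", name, exc)
        report.stages[name] = {"status": "error", "error": str(exc),
                               "traceback": traceback.format_exc(),
                               "elapsed_s": round(time.time() - t0, 2)}
        return None


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute simulate -> render -> analyze -> score for one config.

    Idempotent for a fixed seed; stage failures are recorded in the report
    without aborting stages that do not depend on them.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report = RunReport(config=dataclasses.asdict(config))
    ap = config.analysis_params
    sc = config.to_scenario()

    def model_stage():
        grid = np.linspace(0.0, translocation.DEFAULT_TRANSLOCATION.R_max,
                           200)
        curve = prozone.activity_vs_R(grid)
        prozone.curve_to_frame(curve).to_csv(outdir / "activity_curve.csv",
                                             index=False)
        opt = prozone.find_optimum(curve)
        report.metrics["R_x_opt_uM"] = opt[0]
        report.metrics["activity_opt_uM"] = opt[1]
        report.metrics["below_baseline_crossing_uM"] = opt[2]
        return curve

    def render_stage():
        movie, gt = synthetic.render_movie(sc)
        synthetic.save_movie(movie, gt, outdir / "movie")
        return movie, gt

    _stage(report, "model", model_stage)
    rendered = _stage(report, "render", render_stage)
    if rendered is None:
        report.to_json(outdir / "report.json")
        return report
    movie, gt = rendered

    def analyze_stage():
        out = {}
        if sc.on_chip:
            tracks = track_chip_nuclei(movie, sc.n_cells,
                                       ap["nuclear_threshold"],
                                       gt.dark_frame,
                                       t_min=np.asarray(gt.t_min),
                                       pixel_size=gt.pixel_size)
            disp = np.stack([tr.displacement_um for tr in tracks])
            pd.DataFrame(disp, columns=[f"t{t:g}" for t in gt.t_min]) \
                .to_csv(outdir / "nuclear_displacement_um.csv", index=False)
            out["tracks"] = tracks
            out["profiles"] = analyze_chip_profiles(
                movie, gt.dark_frame, ap["segmentation_threshold"])
        else:
            fret = analyze_fret_movie(movie, gt.dark_frame,
                                      ap["segmentation_threshold"],
                                      ap["min_expression"])
            pd.DataFrame(fret["ratio_series"],
                         columns=[f"t{t:g}" for t in gt.t_min]) \
                .to_csv(outdir / "ratio_series.csv", index=False)
            out["fret"] = fret
            if "mCherry" in movie:
                out["cyto"] = analyze_cytoplasm(
                    movie, gt.dark_frame, ap["segmentation_threshold"],
                    ap["erosion_depth"])
        return out

    analyzed = _stage(report, "analyze", analyze_stage)
    if analyzed is None:
        report.to_json(outdir / "report.json")
        return report

    def score_stage():
        if sc.on_chip:
            tracks = analyzed["tracks"]
            gt_rows = np.array([c["nuclear_row"] for c in gt.cells],
                               dtype=float)
            rec_rows = np.stack([tr.y_px for tr in tracks])
            err_px = np.nanmax(np.abs(rec_rows - gt_rows))
            report.metrics["nuclear_row_error_px"] = float(err_px)
            report.passes["nuclear_tracking_1px"] = bool(err_px <= 1.0)
            disp = np.stack([tr.displacement_um for tr in tracks])
            stats = imaging.population_stats(disp)
            report.metrics["final_mean_displacement_um"] = \
                float(stats.mean[-1])
        else:
            fret = analyzed["fret"]
            gt_ratio = np.array([c["ratio"] for c in gt.cells], dtype=float)
            rec = fret["ratio_series"][fret["kept_ids"]]
            rms = float(np.sqrt(np.nanmean((rec - gt_ratio[fret["kept_ids"]])
                                           ** 2)))
            report.metrics["ratio_rms_error"] = rms
            report.passes["ratio_rms_lt_0.01"] = bool(rms < 0.01)
            mean_inc = float(np.mean(fret["max_increase_pct"]))
            report.metrics["mean_max_ratio_increase_pct"] = mean_inc
            if sc.kind == "fsk_ibmx_saturating":
                dr_pct = translocation.DEFAULT_CALIBRATION.DR * 100
                report.passes["dynamic_range_recovered"] = \
                    bool(abs(mean_inc - dr_pct) <= 1.5)
            if sc.kind == "dmso_control":
                report.passes["no_response_in_control"] = \
                    bool(abs(mean_inc) < 1.0)
        return True

    _stage(report, "score", score_stage)
    report.to_json(outdir / "report.json")
    return report
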