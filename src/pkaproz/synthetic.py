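"""Seeded synthetic-microscopy generator with ground truth.

Renders multi-channel fluorescence movies with the statistical structure
the analysis pipeline assumes — cells with a bright membrane rim,
cytoplasm and nucleus; dose-dependent cytoplasmic depletion of the tagged
regulatory subunit; a FRET-emission/CFP pair encoding a calibrated,
saturating emission-ratio field; a dye channel visualizing the linear
source-sink gradient; and nuclei undergoing 1D biased random-walk
migration with condition-dependent reversal.  Pixels are dark offset +
Poisson(signal) + Gaussian read noise.  Every draw comes from one
per-scenario stream, so identical (scenario, seed) gives bit-identical
output; the imposed quantities are recorded in a ground-truth object
sufficient to score every analysis output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from . import gradient as gradient_mod
from . import prozone, translocation
from .imaging import DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "Scenario",
    "MigrationParams",
    "GroundTruth",
    "MigrationTracks",
    "SCENARIO_KINDS",
    "render_movie",
    "make_migration_tracks",
    "fixture_suite",
    "save_movie",
    "load_movie",
]

SCENARIO_KINDS = (
    "dish_uniform",
    "fsk_ibmx_saturating",
    "chip_gradient",
    "chip_uniform",
    "dmso_control",
    "no_membrane_anchor_control",
)

# rendering constants (expected photon counts and camera model)
DARK_OFFSET = 100.0
READ_NOISE_SD = 3.0
I_EXPR = 800.0   # expression / PKA-R channel base, photons
I_CFP = 900.0    # FRET donor channel base
I_NUC = 1500.0   # nuclear marker in CFP (chip scenarios)
I_DYE_BASE = 200.0
I_DYE_GAIN = 40.0  # photons per nM of dye-visualized rapamycin
BASE_RATIO = 1.2   # resting FRET/CFP emission ratio
RIM_WIDTH_PX = 3
RIM_GAIN_PER_UM = 1.5  # rim brightening per µM translocated R
EXPRESSION_SIGMA = 0.5  # lognormal spread of per-cell expression
SAT_RAMP_MIN = 6.0  # minutes for the saturating stimulus to reach full scale

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Scenario:
    """A named imaging experiment to emulate.

    kind : one of SCENARIO_KINDS.  dose_nM applies to the uniform kinds;
    c_source/c_sink to chip_gradient (and the chip controls, where they
    set the dye channel).  noise scales both shot and read noise (0 turns
    noise off entirely).  frame_interval defaults to 2 min for FRET-type
    scenarios and 1 min for translocation tracking.
    """

    kind: str
    n_cells: int = 12
    duration_min: float = 30.0
    frame_interval_min: float | None = None
    dose_nM: float = 0.0
    c_source: float = 0.0
    c_sink: float = 0.0
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; valid: "
                             f"{', '.join(SCENARIO_KINDS)}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    @property
    def interval(self) -> float:
        if self.frame_interval_min is not None:
            return self.frame_interval_min
        return 1.0 if self.kind == "dish_uniform" else 2.0

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round(self.duration_min / self.interval)) + 1
        return np.arange(n) * self.interval

    @property
    def on_chip(self) -> bool:
        return self.kind in ("chip_gradient", "chip_uniform",
                             "no_membrane_anchor_control")


@dataclass(frozen=True)
class MigrationParams:
    """1D biased random walk of the nucleus in a cross-channel.

    v0 : mean migration speed (µm/min); sigma_step : positional noise per
    frame (µm); p_up_init : initial fraction of source-ward polarized
    cells; tau_range : per-cell reversal-time window (min) in gradient
    scenarios; randomize_interval : repolarization interval (min) under a
    saturating uniform dose.
    """

    v0: float = 0.3
    sigma_step: float = 1.0
    p_up_init: float = 0.8
    tau_range: tuple[float, float] = (15.0, 60.0)
    randomize_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.sigma_step < 0:
            raise ValueError("v0 and sigma_step must be >= 0")
        if not 0 <= self.p_up_init <= 1:
            raise ValueError("p_up_init must be in [0, 1]")


@dataclass
class GroundTruth:
    """Everything imposed by the generator, for scoring recovered values."""

    scenario: dict
    pixel_size: float
    dark_frame: float
    t_min: list
    channels: list
    cells: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1,
                                         default=_jsonable))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass(frozen=True)
class MigrationTracks:
    """Ground-truth nuclear trajectories of a scenario population."""

    t_min: np.ndarray
    y_um: np.ndarray        # (n_cells, T), absolute position, y=0 at sink
    polarity: np.ndarray    # (n_cells, T), +1 toward source
    reversal_time: np.ndarray  # per cell; NaN if never reversed

    @property
    def displacement_um(self) -> np.ndarray:
        return self.y_um - self.y_um[:, [0]]


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse(shape, center, radii):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (((rr - center[0]) / radii[0]) ** 2
            + ((cc - center[1]) / radii[1]) ** 2) <= 1.0


def _stadium(shape, center_row, col_lo, col_hi, half_len):
    """Channel-filling rectangle with rounded caps (a 1D cell body)."""
    width = col_hi - col_lo
    rad = width / 2.0
    cc_mid = (col_lo + col_hi - 1) / 2.0
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    dr = np.maximum(np.abs(rr - center_row) - (half_len - rad), 0.0)
    return (dr ** 2 + (cc - cc_mid) ** 2) <= rad ** 2


def _rim_and_core(footprint):
    core = ndimage.binary_erosion(footprint, structure=_STRUCT8,
                                  iterations=RIM_WIDTH_PX)
    return footprint & ~core, core


# ---------------------------------------------------------------------------
# imposed signal models

def _activity_interp(n_grid: int = 400, r_max: float = None):
    """Fast activity(R_x) lookup from a dense solve of the prozone model."""
    p = translocation.DEFAULT_TRANSLOCATION
    r_hi = p.R_max if r_max is None else r_max
    grid = np.linspace(0.0, r_hi, n_grid)
    curve = prozone.activity_vs_R(grid)
    return lambda rx: np.interp(rx, grid, curve.activity), curve.baseline


def _imposed_ratio_uniform(dose_nM, t_grid):
    """Cell-level imposed ratio trace for a uniform dose."""
    act_of, baseline = _activity_interp()
    rx = translocation.membrane_R_timecourse(dose_nM, t_grid).value
    act = act_of(rx)
    cal = translocation.DEFAULT_CALIBRATION
    frac = cal.DR * (cal.saturation(act) - float(cal.saturation(baseline)))
    return rx, BASE_RATIO * (1.0 + frac)


def _imposed_ratio_saturating(t_grid):
    """Full-scale ramp to the calibrated dynamic range (Fsk/IBMX)."""
    cal = translocation.DEFAULT_CALIBRATION
    g = np.minimum(np.asarray(t_grid, dtype=float) / SAT_RAMP_MIN, 1.0)
    return BASE_RATIO * (1.0 + cal.DR * g)


# ---------------------------------------------------------------------------
# rendering

def _emit(rng, signal, noise_scale):
    """Camera model: dark offset + Poisson(signal) + Gaussian read noise."""
    if noise_scale == 0:
        return DARK_OFFSET + signal
    shot = rng.poisson(signal / noise_scale ** 2) * noise_scale ** 2 \
        if noise_scale != 1.0 else rng.poisson(signal).astype(float)
    read = rng.normal(0.0, READ_NOISE_SD * noise_scale, size=signal.shape)
    return np.maximum(DARK_OFFSET + shot + read, 0.0)


def render_movie(sc: Scenario,
                 mp: MigrationParams = MigrationParams()):
    """Render a scenario into per-channel frame stacks plus ground truth.

    Returns ``(movie, gt)`` where ``movie`` maps channel name to a
    (T, H, W) float array and ``gt`` is the :class:`GroundTruth` record.
    Identical (scenario, seed) yields bit-identical arrays.
    """
    rng = np.random.default_rng(sc.seed)
    if sc.on_chip:
        return _render_chip(sc, mp, rng)
    return _render_dish(sc, rng)


def _render_dish(sc: Scenario, rng):
    t_grid = sc.t_grid
    n = sc.n_cells
    ncols = min(4, n)
    nrows = -(-n // ncols)
    tile = 110
    H, W = nrows * tile, ncols * tile
    translocating = sc.kind == "dish_uniform" and sc.dose_nM > 0

    if sc.kind == "fsk_ibmx_saturating":
        ratio_t = _imposed_ratio_saturating(t_grid)
        rx_t = np.zeros_like(t_grid)
    elif sc.kind in ("dish_uniform", "dmso_control"):
        dose = sc.dose_nM if sc.kind == "dish_uniform" else 0.0
        rx_t, ratio_t = _imposed_ratio_uniform(dose, t_grid)
    else:  # pragma: no cover - guarded by Scenario validation
        raise ValueError(sc.kind)

    cells = []
    expr_map = np.zeros((H, W))
    cyto_weight = np.zeros((H, W))  # cytoplasm+nucleus region per cell expr
    rim_weight = np.zeros((H, W))
    for i in range(n):
        r0 = (i // ncols) * tile + tile // 2 + rng.integers(-5, 6)
        c0 = (i % ncols) * tile + tile // 2 + rng.integers(-5, 6)
        radii = (rng.uniform(24, 30), rng.uniform(30, 38))
        foot = _ellipse((H, W), (r0, c0), radii)
        rim, core = _rim_and_core(foot)
        e = float(rng.lognormal(0.0, EXPRESSION_SIGMA))
        expr_map[foot] = e
        cyto_weight[core] = e
        rim_weight[rim] = e
        cells.append({
            "id": i, "center_rc": [int(r0), int(c0)],
            "radii_px": [float(radii[0]), float(radii[1])],
            "area_px": int(foot.sum()), "expression": e,
            "r_x_uM": rx_t.tolist(), "ratio": ratio_t.tolist(),
        })

    p = translocation.DEFAULT_TRANSLOCATION
    channels = {"YFP": [], "mCherry": [], "CFP": [], "FRET_em": []}
    for k, t in enumerate(t_grid):
        rx = rx_t[k]
        depl = rx / p.R_cyto_total if translocating else 0.0
        yfp = I_EXPR * expr_map
        mch = I_EXPR * (cyto_weight * (1.0 - depl)
                        + rim_weight * (1.0 + RIM_GAIN_PER_UM * rx))
        cfp = I_CFP * expr_map
        fret = cfp * ratio_t[k]
        for name, sig in (("YFP", yfp), ("mCherry", mch),
                          ("CFP", cfp), ("FRET_em", fret)):
            channels[name].append(_emit(rng, sig, sc.noise))

    movie = {name: np.stack(frames) for name, frames in channels.items()}
    gt = GroundTruth(scenario=_scenario_dict(sc),
                     pixel_size=DEFAULT_PIXEL_SIZE_UM,
                     dark_frame=DARK_OFFSET, t_min=t_grid.tolist(),
                     channels=sorted(movie), cells=cells)
    return movie, gt


def _render_chip(sc: Scenario, mp: MigrationParams, rng):
    t_grid = sc.t_grid
    geom = gradient_mod.DEFAULT_GEOMETRY
    px = DEFAULT_PIXEL_SIZE_UM
    H = int(round(geom.L / px)) + 1  # row 0 = source end (+y up)
    chan_w, wall = 20, 5
    pitch = chan_w + 2 * wall
    W = sc.n_cells * pitch
    translocates = sc.kind != "no_membrane_anchor_control"

    if sc.kind == "chip_uniform":
        c_source = c_sink = sc.dose_nM
    else:
        c_source, c_sink = sc.c_source, sc.c_sink
    profile = gradient_mod.steady_state_profile(c_source, c_sink, geom)

    tracks = make_migration_tracks(sc, mp, rng=rng)
    act_of, baseline = _activity_interp()
    cal = translocation.DEFAULT_CALIBRATION
    s0 = float(cal.saturation(baseline))
    p = translocation.DEFAULT_TRANSLOCATION

    half_len_px = int(round(25.0 / px))  # 50 µm cell
    cells = []
    footprints = []
    for i in range(sc.n_cells):
        col_lo = i * pitch + wall
        row0 = int(round((geom.L - tracks.y_um[i, 0]) / px))
        e = float(rng.lognormal(0.0, EXPRESSION_SIGMA))
        cells.append({
            "id": i, "channel_cols": [col_lo, col_lo + chan_w],
            "row0": row0, "half_len_px": half_len_px, "expression": e,
            "nuclear_row": [], "ratio_mean": [],
            "y_um": tracks.y_um[i].tolist(),
            "polarity": tracks.polarity[i].tolist(),
            "reversal_time": (None if math.isnan(tracks.reversal_time[i])
                              else float(tracks.reversal_time[i])),
        })
        footprints.append((col_lo, row0, e))

    # dye channel is static: gradient visualized by a tracer dye
    rows_y_um = geom.L - np.arange(H) * px  # +y (toward source) = row 0
    dye_sig = np.tile((I_DYE_BASE
                       + I_DYE_GAIN * profile.at(rows_y_um))[:, None], (1, W))

    # The nuclear marker (CFP filter set) and the FRET donor (also CFP)
    # come from separate experiments on the device; they are emitted as
    # separate channels so each analysis path sees its own signal.
    channels = {"YFP": [], "CFP": [], "CFP_donor": [], "FRET_em": [],
                "dye": []}
    for k, t in enumerate(t_grid):
        yfp = np.zeros((H, W))
        cfp = np.zeros((H, W))
        donor = np.zeros((H, W))
        fret = np.zeros((H, W))
        for i, (col_lo, row0, e) in enumerate(footprints):
            nuc_row = int(round((geom.L - tracks.y_um[i, k]) / px))
            nuc_row = min(max(nuc_row, 12), H - 13)
            cells[i]["nuclear_row"].append(nuc_row)
            body_row = nuc_row  # body follows the nucleus
            foot = _stadium((H, W), body_row, col_lo, col_lo + chan_w,
                            half_len_px)
            yfp[foot] += I_EXPR * e
            nuc = _ellipse((H, W), (nuc_row, col_lo + chan_w / 2 - 0.5),
                           (11, 7))
            cfp[nuc] += I_NUC
            # FRET body with a per-row imposed ratio from the local dose
            rows = np.nonzero(foot.any(axis=1))[0]
            if translocates:
                doses = profile.at(geom.L - rows * px)
                occ = doses ** p.h / (doses ** p.h + p.EC50 ** p.h)
                rx = p.R_max * occ * (1.0 - np.exp(-p.k_max * occ * t))
                frac = cal.DR * (cal.saturation(act_of(rx)) - s0)
            else:
                frac = np.zeros(rows.size)
            ratio_rows = BASE_RATIO * (1.0 + frac)
            body_cfp = I_CFP * e
            npx_row = foot[rows].sum(axis=1)
            cells[i]["ratio_mean"].append(
                float((ratio_rows * npx_row).sum() / npx_row.sum()))
            for r, ratio in zip(rows, ratio_rows):
                line = foot[r]
                fret[r, line] += body_cfp * ratio
            donor[foot] += body_cfp
        for name, sig in (("YFP", yfp), ("CFP", cfp), ("CFP_donor", donor),
                          ("FRET_em", fret), ("dye", dye_sig)):
            channels[name].append(_emit(rng, sig, sc.noise))

    movie = {name: np.stack(frames) for name, frames in channels.items()}
    gt = GroundTruth(scenario=_scenario_dict(sc),
                     pixel_size=px, dark_frame=DARK_OFFSET,
                     t_min=t_grid.tolist(), channels=sorted(movie),
                     cells=cells)
    return movie, gt


def _scenario_dict(sc: Scenario) -> dict:
    d = asdict(sc)
    d["frame_interval_min"] = sc.interval
    return d


# ---------------------------------------------------------------------------
# migration

def _reversal_rule(sc: Scenario) -> str:
    if sc.kind == "chip_gradient" and sc.c_source != sc.c_sink:
        return "flip"
    if sc.kind == "chip_uniform" and sc.dose_nM >= 50:
        return "randomize"
    return "none"


def make_migration_tracks(sc: Scenario,
                          mp: MigrationParams = MigrationParams(),
                          rng=None) -> MigrationTracks:
    """1D biased random-walk nuclear trajectories for a scenario.

    y(t+dt) = y(t) + s(t) v0 dt + Normal(0, sigma_step^2), with reflecting
    boundaries inside the cross-channel.  The polarity s evolves by the
    scenario's rule: in a gradient with translocation each cell flips to
    the sink-ward direction at its own reversal time tau ~ U(tau_range);
    under a saturating uniform dose polarity is resampled at random every
    ``randomize_interval`` minutes; controls never flip.
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    t = sc.t_grid
    n, T = sc.n_cells, t.size
    dt = sc.interval
    rule = _reversal_rule(sc)
    L = gradient_mod.DEFAULT_GEOMETRY.L
    margin = 25.0

    s = np.where(rng.random(n) < mp.p_up_init, 1.0, -1.0)
    tau = rng.uniform(*mp.tau_range, size=n) if rule == "flip" \
        else np.full(n, np.nan)
    next_flip = rng.uniform(0.0, mp.randomize_interval, size=n) \
        if rule == "randomize" else None

    y = np.empty((n, T))
    pol = np.empty((n, T))
    y[:, 0] = 125.0 + rng.uniform(-20.0, 20.0, size=n)
    pol[:, 0] = s
    reversed_at = np.full(n, np.nan)
    for k in range(1, T):
        now = t[k]
        if rule == "flip":
            newly = (now >= tau) & (s > 0)
            reversed_at[newly & np.isnan(reversed_at)] = now
            s = np.where(now >= tau, -1.0, s)
        elif rule == "randomize":
            due = now >= next_flip
            if due.any():
                s = np.where(due, np.where(rng.random(n) < 0.5, 1.0, -1.0), s)
                next_flip = np.where(due, next_flip + mp.randomize_interval,
                                     next_flip)
        step = s * mp.v0 * dt + rng.normal(0.0, mp.sigma_step, size=n)
        ynew = y[:, k - 1] + step
        # reflecting boundaries
        ynew = np.where(ynew < margin, 2 * margin - ynew, ynew)
        ynew = np.where(ynew > L - margin, 2 * (L - margin) - ynew, ynew)
        y[:, k] = np.clip(ynew, margin, L - margin)
        pol[:, k] = s
    if rule == "flip":
        reversed_at = np.where(np.isnan(reversed_at) & (tau <= t[-1]),
                               tau, reversed_at)
    return MigrationTracks(t_min=t, y_um=y, polarity=pol,
                           reversal_time=reversed_at)


# ---------------------------------------------------------------------------
# fixtures and I/O

def fixture_suite(seed: int = 0) -> dict:
    """Small deterministic images for unit tests, with a manifest.

    Returns a dict with entries ``disk``, ``two_disks``, ``rim_disk``,
    ``ramp`` and ``translated_nucleus`` plus a ``manifest`` of the values
    each fixture was constructed to have.
    """
    out = {}
    shape = (101, 101)
    disk = np.zeros(shape)
    dmask = _ellipse(shape, (50, 50), (20, 20))
    disk[dmask] = 500.0
    out["disk"] = disk

    two = np.zeros(shape)
    m1 = _ellipse(shape, (30, 30), (10, 10))
    m2 = _ellipse(shape, (70, 70), (10, 10))
    two[m1 | m2] = 500.0
    out["two_disks"] = two

    # disk of radius 50 at 100 with a bright 10-px-wide outer rim at 200
    rshape = (121, 121)
    outer = _ellipse(rshape, (60, 60), (50, 50))
    inner = ndimage.binary_erosion(outer, structure=_STRUCT8, iterations=10)
    rim_disk = np.zeros(rshape)
    rim_disk[outer] = 200.0
    rim_disk[inner] = 100.0
    out["rim_disk"] = rim_disk

    # rectangular cell with an affine ratio ramp along rows
    H, W = 40, 60
    cfp = np.full((H, W), 500.0)
    ramp_ratio = 1.0 + 0.01 * np.arange(H)[:, None]
    out["ramp_cfp"] = cfp
    out["ramp_fret"] = cfp * ramp_ratio

    frames = []
    for k in range(6):
        img = np.zeros((64, 64))
        img[_ellipse((64, 64), (40 - 3 * k, 32), (6, 6))] = 800.0
        frames.append(img)
    out["translated_nucleus"] = np.stack(frames)

    out["manifest"] = {
        "disk_area_px": int(dmask.sum()),
        "disk_centroid_rc": [50.0, 50.0],
        "two_disk_centroids_rc": [[30.0, 30.0], [70.0, 70.0]],
        "rim_disk_core_mean": 100.0,
        "ramp_row_ratio": "1 + 0.01*row",
        "nucleus_shift_px_per_frame": -3,
        "nucleus_displacement_um_frame5": 15 * DEFAULT_PIXEL_SIZE_UM,
        "seed": seed,
    }
    return out


def save_movie(movie: dict, gt: GroundTruth, outdir) -> dict:
    """Write one multi-page TIFF per channel plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, stack in movie.items():
        path = outdir / f"{name}.tif"
        tifffile.imwrite(path, stack.astype(np.float32),
                         photometric="minisblack")
        paths[name] = str(path)
    gt.to_json(outdir / "ground_truth.json")
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths


def load_movie(indir) -> tuple[dict, GroundTruth]:
    """Read back a movie directory written by :func:`save_movie`."""
    indir = Path(indir)
    gt = GroundTruth.from_json(indir / "ground_truth.json")
    movie = {name: np.asarray(tifffile.imread(indir / f"{name}.tif"),
                              dtype=float)
             for name in gt.channels}
    return movie, gt
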