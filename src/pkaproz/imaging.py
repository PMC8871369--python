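"""Single-cell image analysis for ratiometric FRET movies.

Implements the analysis chain used on the fluorescence movies: intensity
thresholding in the expression channel for segmentation, dark-frame
corrected FRET/CFP emission ratio, cytoplasmic intensity tracking after
eroding away the outermost 20 pixels (7.78 µm) of each cell, nuclear
centroid tracking along the gradient axis, 20-bin intracellular ratio
profiles, and population statistics (mean, SEM, pooled-variance two-tailed
Student's t-test).

Coordinate convention: images are row-major with 0-based indices; a
decreasing row index points toward the gradient source (+y).  Everything
here is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "ImageFrame",
    "CellMask",
    "RatioMap",
    "NuclearTrack",
    "BinnedProfile",
    "PopulationSeries",
    "CellMeanResult",
    "CytoplasmSeries",
    "threshold_segment",
    "fret_ratio_map",
    "cell_mean_ratio",
    "cytoplasmic_intensity_series",
    "nuclear_displacement",
    "bin_profile",
    "population_stats",
    "two_sample_ttest",
]

log = logging.getLogger(__name__)

#: µm per pixel, from the 20 px = 7.78 µm erosion depth of the protocol
DEFAULT_PIXEL_SIZE_UM = 0.389

#: connected components smaller than this are discarded as debris
MIN_CELL_AREA_PX = 50

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity unit disk


@dataclass(frozen=True)
class ImageFrame:
    """One acquired channel image with its dark-frame offset."""

    pixels: np.ndarray
    channel: str = ""
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    t: float = 0.0
    dark_frame: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("pixels must be finite and non-negative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        df = self.dark_frame
        if np.ndim(df) not in (0, 2):
            raise ValueError("dark_frame must be a scalar or 2D array")
        if np.ndim(df) == 2 and np.shape(df) != px.shape:
            raise ValueError("dark_frame shape must match pixels")

    @property
    def corrected(self) -> np.ndarray:
        """Dark-frame subtracted intensities."""
        return self.pixels - np.asarray(self.dark_frame, dtype=float)


@dataclass(frozen=True)
class CellMask:
    """Boolean footprint of one segmented cell."""

    mask: np.ndarray
    cell_id: int

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())


@dataclass(frozen=True)
class RatioMap:
    """Per-pixel FRET/CFP ratio, defined only inside cells where valid."""

    values: np.ndarray
    defined: np.ndarray  # boolean; False outside masks or denominator <= 0


@dataclass(frozen=True)
class NuclearTrack:
    """Nuclear centroid track along the gradient axis for one cell."""

    cell_id: int
    t: np.ndarray  # min
    y_px: np.ndarray  # centroid row; NaN where missing
    displacement_um: np.ndarray  # +y toward source; NaN where missing
    missing: np.ndarray  # bool per frame


@dataclass(frozen=True)
class BinnedProfile:
    """20-bin intracellular profile along the gradient axis."""

    positions: np.ndarray  # normalized bin centers, 0 = high-rapamycin end
    means: np.ndarray  # NaN where a bin had no defined pixel
    empty: np.ndarray  # bool per bin


@dataclass(frozen=True)
class PopulationSeries:
    """Per-time-point population mean, SEM and cell count."""

    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray


@dataclass(frozen=True)
class CellMeanResult:
    """Cell-mean ratio, or an explicit exclusion with its reason."""

    value: float | None
    excluded: bool = False
    reason: str = ""


@dataclass(frozen=True)
class CytoplasmSeries:
    """Normalized cytoplasmic intensity series, or an exclusion."""

    series: np.ndarray | None
    excluded: bool = False
    reason: str = ""


def threshold_segment(frame: ImageFrame, threshold: float,
                      min_area: int = MIN_CELL_AREA_PX) -> list[CellMask]:
    """Segment cells as 8-connected components above an intensity threshold.

    Components smaller than ``min_area`` pixels are discarded as debris;
    the survivors are ordered by centroid (row, then column) and assigned
    sequential ids.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    labels = measure.label(frame.pixels > threshold, connectivity=2)
    masks = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        masks.append((region.centroid, labels == region.label))
    masks.sort(key=lambda item: item[0])
    return [CellMask(mask=m, cell_id=i) for i, (_, m) in enumerate(masks)]


def fret_ratio_map(fret_frame: ImageFrame, cfp_frame: ImageFrame,
                   masks: list[CellMask]) -> RatioMap:
    """Per-pixel (FRET - DF) / (CFP - DF) inside the given cell masks.

    Pixels outside every mask, or whose dark-corrected denominator is not
    strictly positive, are undefined and excluded from downstream means.
    """
    if fret_frame.pixels.shape != cfp_frame.pixels.shape:
        raise ValueError("FRET and CFP frames must have the same shape")
    num = fret_frame.corrected
    den = cfp_frame.corrected
    inside = np.zeros(num.shape, dtype=bool)
    for m in masks:
        inside |= m.mask
    defined = inside & (den > 0)
    values = np.full(num.shape, np.nan)
    values[defined] = num[defined] / den[defined]
    return RatioMap(values=values, defined=defined)


def cell_mean_ratio(rmap: RatioMap, mask: CellMask,
                    expression_frame: ImageFrame | None = None,
                    min_expression: float = 0.0) -> CellMeanResult:
    """Mean ratio over a cell's defined pixels, with an expression filter.

    Cells whose mean expression-channel intensity is below
    ``min_expression`` are excluded rather than reported, mirroring the
    probe-expression exclusion of the protocol.
    """
    if expression_frame is not None:
        expr = float(expression_frame.pixels[mask.mask].mean())
        if expr < min_expression:
            return CellMeanResult(None, excluded=True,
                                  reason=f"expression {expr:.1f} below "
                                         f"threshold {min_expression:.1f}")
    sel = mask.mask & rmap.defined
    if not sel.any():
        return CellMeanResult(None, excluded=True,
                              reason="no defined ratio pixels in mask")
    return CellMeanResult(float(rmap.values[sel].mean()))


def cytoplasmic_intensity_series(frames: np.ndarray, masks: np.ndarray,
                                 erosion_depth: int = 20) -> CytoplasmSeries:
    """Cytoplasmic (non-membrane) intensity of one cell over time.

    Per frame, the segmentation mask is eroded by ``erosion_depth``
    iterations of the single-pixel 8-connectivity element — stripping the
    outermost 20 pixels (7.78 µm), i.e. the membrane-proximal rim — and
    the strictly positive intensities inside the eroded mask are averaged.
    The series is normalized to its t = 0 value, so the reported
    "cytoplasmic intensity drop" is 1 minus this series.

    Parameters
    ----------
    frames : (T, H, W) array
        Tracking-channel (e.g. mCherry) intensities.
    masks : (T, H, W) boolean array
        Whole-cell segmentation per frame.
    """
    if erosion_depth < 0:
        raise ValueError("erosion_depth must be >= 0")
    frames = np.asarray(frames, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    if frames.shape != masks.shape:
        raise ValueError("frames and masks must have the same shape")
    out = np.empty(frames.shape[0])
    for i, (img, m) in enumerate(zip(frames, masks)):
        core = ndimage.binary_erosion(m, structure=_STRUCT8,
                                      iterations=erosion_depth) \
            if erosion_depth else m
        vals = img[core]
        vals = vals[vals > 0]
        if vals.size == 0:
            reason = (f"eroded mask empty at frame {i}: cell thinner than "
                      f"{2 * erosion_depth + 1} px")
            log.warning(reason)
            return CytoplasmSeries(None, excluded=True, reason=reason)
        out[i] = vals.mean()
    if out[0] == 0:
        return CytoplasmSeries(None, excluded=True,
                               reason="zero intensity at t = 0")
    return CytoplasmSeries(out / out[0])


def nuclear_displacement(frames: np.ndarray, threshold: float,
                         t: np.ndarray | None = None,
                         pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                         cell_id: int = 0) -> NuclearTrack:
    """Track the nuclear centroid row and its displacement along +y.

    Per frame, the nucleus is the largest 8-connected component above
    ``threshold`` (multiple components are logged, the largest kept).
    Displacement is (row(0) - row(t)) * pixel_size, positive toward the
    source side (decreasing row).  Frames with no component are flagged
    missing; no interpolation is performed.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    y_px = np.full(n, np.nan)
    missing = np.zeros(n, dtype=bool)
    for i, img in enumerate(frames):
        labels = measure.label(img > threshold, connectivity=2)
        regions = measure.regionprops(labels)
        if not regions:
            missing[i] = True
            continue
        if len(regions) > 1:
            log.info("cell %d frame %d: %d nuclear components, keeping "
                     "largest", cell_id, i, len(regions))
        largest = max(regions, key=lambda r: r.area)
        y_px[i] = largest.centroid[0]
    if missing[0]:
        displacement = np.full(n, np.nan)
    else:
        displacement = (y_px[0] - y_px) * pixel_size
    return NuclearTrack(cell_id=cell_id, t=t, y_px=y_px,
                        displacement_um=displacement, missing=missing)


def bin_profile(rmap: RatioMap, mask: CellMask, axis: str = "row",
                n_bins: int = 20, high_end: str = "min") -> BinnedProfile:
    """Mean ratio in ``n_bins`` equal-width bins along the gradient axis.

    The mask's bounding extent along ``axis`` ('row' or 'col') is split
    into equal-width bins and defined ratio pixels averaged per bin.
    Normalized positions run from 0 at the high-rapamycin end to 1 at the
    low end; ``high_end='min'`` places the high-rapamycin end at the
    smaller index (the default, matching rows decreasing toward the
    source).
    """
    if axis not in ("row", "col"):
        raise ValueError(f"axis must be 'row' or 'col', got {axis!r}")
    rows, cols = np.nonzero(mask.mask)
    coord = rows if axis == "row" else cols
    lo, hi = int(coord.min()), int(coord.max())
    extent = hi - lo + 1
    if extent < n_bins:
        raise ValueError(f"mask extent {extent} px along {axis} is below "
                         f"{n_bins} bins")
    sel = mask.mask & rmap.defined
    rr, cc = np.nonzero(sel)
    c = rr if axis == "row" else cc
    # bin index in [0, n_bins); the high-rapamycin end maps to bin 0
    idx = np.minimum(((c - lo) * n_bins) // extent, n_bins - 1).astype(int)
    if high_end == "max":
        idx = n_bins - 1 - idx
    elif high_end != "min":
        raise ValueError("high_end must be 'min' or 'max'")
    vals = rmap.values[sel]
    means = np.full(n_bins, np.nan)
    empty = np.ones(n_bins, dtype=bool)
    for b in range(n_bins):
        in_bin = vals[idx == b]
        if in_bin.size:
            means[b] = in_bin.mean()
            empty[b] = False
    positions = (np.arange(n_bins) + 0.5) / n_bins
    return BinnedProfile(positions=positions, means=means, empty=empty)


def population_stats(series: np.ndarray) -> PopulationSeries:
    """Mean, SEM and n per time point over a (cells x time) array.

    NaN entries (missing cells at a time point) are ignored; SEM uses the
    n-1 sample standard deviation.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("expected a 2D (cells x time) array")
    n = np.sum(~np.isnan(series), axis=0)
    if np.any(n < 1):
        raise ValueError("every time point needs at least one cell")
    mean = np.nanmean(series, axis=0)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(series, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(n), np.nan)
    return PopulationSeries(mean=mean, sem=sem, n=n)


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Two-tailed pooled-variance Student's t-test between two groups.

    Degenerate zero-variance groups are handled explicitly: identical
    constant groups give (0, 1); distinct constants give (inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for the t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf * math.copysign(1, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
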