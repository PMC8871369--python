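"""Source-sink diffusion gradient in the microfluidic cross-channels.

Cells sit in narrow cross-channels spanning a continuously replenished
sink (y = 0) and source (y = L) channel.  High hydraulic resistance keeps
the cross-channels flow-free, so rapamycin moves by pure diffusion and the
steady state is the affine solution of Laplace's equation in 1D.  The span
L = 250 µm reproduces both printed device conditions: 0-20 nM at
0.08 nM/µm and 10-20 nM at 0.04 nM/µm.

Composing the local dose seen along a cell's length with the translocation
and prozone models predicts the intracellular activity profile: early
after gradient onset, activity is higher at the high-rapamycin (source)
end; once the front end crosses the prozone optimum the internal activity
gradient reverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import prozone, translocation
from .prozone import BindingParams, CompartmentTotals
from .translocation import TranslocationParams

__all__ = [
    "DeviceGeometry",
    "GradientProfile",
    "CellSpan",
    "DEFAULT_GEOMETRY",
    "GRADIENT_PRESETS",
    "steady_state_profile",
    "transient_profile",
    "predicted_cell_profile",
    "polarity_score",
]


@dataclass(frozen=True)
class DeviceGeometry:
    """Cross-channel geometry and solute diffusivity.

    L : sink-to-source span (µm).  n_channels : parallel cross-channels.
    D_rap : rapamycin diffusivity (µm²/s), small-molecule scale; only the
    transient depends on it.
    """

    L: float = 250.0
    n_channels: int = 304
    D_rap: float = 300.0

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if not self.D_rap > 0:
            raise ValueError(f"D_rap must be positive, got {self.D_rap}")


@dataclass(frozen=True)
class GradientProfile:
    """1D concentration field between sink (y=0) and source (y=L)."""

    y_grid: np.ndarray  # µm
    c: np.ndarray  # nM
    slope: float  # nM/µm, positive = increasing toward source
    c_sink: float
    c_source: float

    def at(self, y) -> np.ndarray:
        """Concentration at arbitrary positions by linear interpolation."""
        return np.interp(np.asarray(y, dtype=float), self.y_grid, self.c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y_um": self.y_grid, "c_nM": self.c})


@dataclass(frozen=True)
class CellSpan:
    """A cell's extent along the gradient axis.

    y_front is the source-facing end, y_rear the sink-facing end.
    """

    y_front: float
    y_rear: float

    def __post_init__(self) -> None:
        if not (0 <= self.y_rear < self.y_front):
            raise ValueError(
                f"need 0 <= y_rear < y_front, got rear={self.y_rear}, "
                f"front={self.y_front}")

    @property
    def length(self) -> float:
        return self.y_front - self.y_rear


DEFAULT_GEOMETRY = DeviceGeometry()

#: named (c_source, c_sink) boundary pairs (nM)
GRADIENT_PRESETS = {
    "steep": (20.0, 0.0),
    "shallow": (20.0, 10.0),
    "reverse": (0.0, 20.0),
    "uniform-20": (20.0, 20.0),
    "uniform-100": (100.0, 100.0),
    "dmso": (0.0, 0.0),
}


def steady_state_profile(c_source: float, c_sink: float,
                         geom: DeviceGeometry = DEFAULT_GEOMETRY,
                         n_points: int = 101) -> GradientProfile:
    """Steady diffusion profile: affine between the boundary reservoirs.

    c(y) = c_sink + (c_source - c_sink) * y / L;  slope = (c_source - c_sink) / L.
    """
    if c_source < 0 or c_sink < 0:
        raise ValueError("boundary concentrations must be non-negative")
    y = np.linspace(0.0, geom.L, n_points)
    c = c_sink + (c_source - c_sink) * y / geom.L
    return GradientProfile(y, c, slope=(c_source - c_sink) / geom.L,
                           c_sink=c_sink, c_source=c_source)


def transient_profile(c_source: float, c_sink: float,
                      geom: DeviceGeometry = DEFAULT_GEOMETRY,
                      t: float = 0.0, n_points: int = 101,
                      term_tol: float = 1e-9,
                      max_terms: int = 200_000) -> GradientProfile:
    """Diffusion transient from a solute-free channel, Dirichlet boundaries.

    Fourier sine series on the steady solution:
    c(y, t) = s(y) - sum_n b_n sin(n pi y / L) exp(-D (n pi / L)^2 t) with
    b_n = (2 / n pi) (c_sink - (-1)^n c_source).  The series is truncated
    once the next term's amplitude falls below ``term_tol`` times the
    concentration scale (or at ``max_terms``; at t = 0 convergence is
    algebraic, so the cap governs there).
    """
    if t < 0:
        raise ValueError(f"t must be non-negative, got {t}")
    steady = steady_state_profile(c_source, c_sink, geom, n_points)
    y = steady.y_grid
    scale = max(c_source, c_sink, 1.0)
    correction = np.zeros_like(y)
    for n in range(1, max_terms + 1):
        b_n = (2.0 / (n * math.pi)) * (c_sink - (-1.0) ** n * c_source)
        decay = math.exp(-geom.D_rap * (n * math.pi / geom.L) ** 2 * t)
        amp = abs(b_n) * decay
        if amp < term_tol * scale:
            break
        correction += b_n * decay * np.sin(n * math.pi * y / geom.L)
    c = steady.c - correction
    return GradientProfile(y, c, slope=steady.slope,
                           c_sink=c_sink, c_source=c_source)


def predicted_cell_profile(span: CellSpan, profile: GradientProfile, t_grid,
                           n_positions: int = 20,
                           p: TranslocationParams = translocation.DEFAULT_TRANSLOCATION,
                           basal: CompartmentTotals = prozone.DEFAULT_BASAL,
                           rho: float = prozone.DEFAULT_RHO,
                           params: BindingParams = prozone.DEFAULT_PARAMS
                           ) -> pd.DataFrame:
    """Predicted membrane PKA activity along a cell exposed to a gradient.

    The cell is sampled at ``n_positions`` bin centers on a normalized axis
    with 0 at the source-facing (high-rapamycin) end and 1 at the
    sink-facing end.  Each position sees the local dose c(y) and follows
    its own activity time course.  Returns a tidy frame with columns
    ``position``, ``t_min``, ``activity``.
    """
    L = profile.y_grid[-1]
    if not (0 <= span.y_rear and span.y_front <= L):
        raise ValueError(f"cell span [{span.y_rear}, {span.y_front}] outside "
                         f"device [0, {L}]")
    positions = (np.arange(n_positions) + 0.5) / n_positions
    t = np.asarray(t_grid, dtype=float)
    rows = []
    for pos in positions:
        y = span.y_front - pos * span.length  # pos 0 -> source-facing end
        dose = float(profile.at(y))
        tc = translocation.activity_timecourse(dose, t, p, basal, rho, params)
        rows.append(pd.DataFrame({"position": pos, "t_min": t,
                                  "activity": tc.value}))
    return pd.concat(rows, ignore_index=True)


def polarity_score(profile_at_t) -> float:
    """Front-half minus rear-half mean activity along the cell axis.

    Accepts either a 1D activity array ordered front (source-facing) to
    rear, or the frame returned by :func:`predicted_cell_profile`
    restricted to one time point.  A positive score predicts migration
    toward the source under the front-high-PKA premise.
    """
    if isinstance(profile_at_t, pd.DataFrame):
        ordered = profile_at_t.sort_values("position")["activity"].to_numpy()
    else:
        ordered = np.asarray(profile_at_t, dtype=float)
    if ordered.size < 2:
        raise ValueError("profile needs at least 2 positions")
    half = ordered.size // 2
    return float(ordered[:half].mean() - ordered[-half:].mean())
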