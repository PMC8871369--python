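"""Equilibrium prozone model of membrane-compartment PKA.

The regulatory subunit (PKA-R) is treated as a linker: each R protomer
carries one binding site for the catalytic subunit (PKA-C) and two sites
for cAMP, with a thermodynamically consistent allosteric penalty ``alpha``
per simultaneously bound (C, cAMP) pair.  At low R the linker assembles
holoenzyme and, via cAMP, releases active C; in excess it titrates C and
cAMP into incomplete complexes, so free catalytic subunit — the activity
readout — is a biphasic function of how much R is recruited to the
membrane.  This is the classical prozone (hook) effect of scaffold-like
molecules applied to the PKA holoenzyme.

Protomers are independent; each occupies one of six microstates
``(c, a)`` with ``c`` bound catalytic subunits (0 or 1) and ``a`` bound
cAMP (0, 1 or 2).  The grand-canonical weight of a microstate at free
ligand concentrations ``C_free``, ``A_free`` is::

    w(c, a) = (C_free/K_C)^c * binom(2, a) * (A_free/K_A)^a * alpha^(-c*a)

The two conservation equations (for total C and total cAMP) are solved by
nested bracketing root finding; each equation is monotone in its own free
variable, so the physical root is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingParams",
    "CompartmentTotals",
    "EquilibriumState",
    "ActivityCurve",
    "ProtomerWeights",
    "DEFAULT_PARAMS",
    "DEFAULT_BASAL",
    "DEFAULT_RHO",
    "protomer_weights",
    "solve_equilibrium",
    "activity_vs_R",
    "find_optimum",
]

#: microstate index grids: c in {0, 1}, a in {0, 1, 2}
_C_STATES = np.array([0, 0, 0, 1, 1, 1], dtype=float)
_A_STATES = np.array([0, 1, 2, 0, 1, 2], dtype=float)
_BINOM_A = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])

_RES_TOL = 1e-12  # absolute residual tolerance of the nested solver


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium constants and allosteric coupling of one R protomer.

    Parameters
    ----------
    K_C : float
        Dissociation constant (µM) of the catalytic subunit from a
        cAMP-free protomer.
    K_A : float
        Per-site cAMP dissociation constant (µM) on a C-free protomer.
    alpha : float
        Allosteric coupling, >= 1: each bound cAMP weakens C binding by a
        factor ``alpha`` (and symmetrically, bound C weakens cAMP binding).
    n_A : int
        cAMP sites per protomer; fixed at 2 for PKA-R.
    """

    K_C: float = 0.01
    K_A: float = 0.1
    alpha: float = 100.0
    n_A: int = 2

    def __post_init__(self) -> None:
        if not (self.K_C > 0 and math.isfinite(self.K_C)):
            raise ValueError(f"K_C must be positive and finite, got {self.K_C}")
        if not (self.K_A > 0 and math.isfinite(self.K_A)):
            raise ValueError(f"K_A must be positive and finite, got {self.K_A}")
        if not (self.alpha >= 1 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")
        if self.n_A != 2:
            raise ValueError(f"n_A is fixed at 2, got {self.n_A}")


@dataclass(frozen=True)
class CompartmentTotals:
    """Conserved totals (µM) in the membrane compartment."""

    R_tot: float
    C_tot: float
    A_tot: float

    def __post_init__(self) -> None:
        for name in ("R_tot", "C_tot", "A_tot"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be non-negative and finite, got {v}")


@dataclass(frozen=True)
class EquilibriumState:
    """Solved free concentrations and per-protomer occupancies."""

    C_free: float
    A_free: float
    mean_c: float  # bound C per protomer, in [0, 1]
    mean_a: float  # bound cAMP per protomer, in [0, 2]
    Z: float  # protomer partition function


@dataclass(frozen=True)
class ProtomerWeights:
    """Microstate weight table of a single protomer at fixed free ligands."""

    weights: np.ndarray  # shape (6,), order (c,a) = 00,01,02,10,11,12
    Z: float
    mean_c: float
    mean_a: float


@dataclass(frozen=True)
class ActivityCurve:
    """Free catalytic subunit as a function of translocated R."""

    R_x_grid: np.ndarray
    activity: np.ndarray
    baseline: float

    def __post_init__(self) -> None:
        if len(self.R_x_grid) != len(self.activity):
            raise ValueError("R_x_grid and activity must have equal length")


# Default membrane compartment.  Baseline R at the plasma membrane is
# sub-optimal: recruiting more R first raises free C, then titrates it.
DEFAULT_PARAMS = BindingParams()
DEFAULT_BASAL = CompartmentTotals(R_tot=0.1, C_tot=0.1, A_tot=1.2)
#: catalytic subunit co-recruited per translocated R protomer
DEFAULT_RHO = 0.5


def protomer_weights(C_free: float, A_free: float,
                     params: BindingParams = DEFAULT_PARAMS) -> ProtomerWeights:
    """Microstate weights w(c, a) of one protomer at fixed free ligands.

    ``w(0, 0) = 1`` by construction; ``Z`` is the sum over the six states
    and ``mean_c``/``mean_a`` the weight-averaged occupancies.
    """
    for name, v in (("C_free", C_free), ("A_free", A_free)):
        if not (math.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be non-negative and finite, got {v}")
    w = ((C_free / params.K_C) ** _C_STATES
         * _BINOM_A * (A_free / params.K_A) ** _A_STATES
         * params.alpha ** (-_C_STATES * _A_STATES))
    Z = float(w.sum())
    return ProtomerWeights(
        weights=w,
        Z=Z,
        mean_c=float((w * _C_STATES).sum() / Z),
        mean_a=float((w * _A_STATES).sum() / Z),
    )


def _c_residual(C_free: float, A_free: float, totals: CompartmentTotals,
                params: BindingParams) -> float:
    mc = protomer_weights(C_free, A_free, params).mean_c
    return C_free + totals.R_tot * mc - totals.C_tot


def _solve_c(A_free: float, totals: CompartmentTotals,
             params: BindingParams) -> float:
    """Free C satisfying C conservation at fixed free cAMP (monotone)."""
    if totals.C_tot == 0:
        return 0.0
    lo, hi = 0.0, totals.C_tot
    if _c_residual(hi, A_free, totals, params) <= 0:
        return hi  # R_tot == 0 and binding negligible
    return brentq(_c_residual, lo, hi, args=(A_free, totals, params),
                  xtol=1e-16, rtol=1e-15, maxiter=200)


def solve_equilibrium(totals: CompartmentTotals,
                      params: BindingParams = DEFAULT_PARAMS,
                      camp_buffered: bool = False) -> EquilibriumState:
    """Solve the two conservation equations for the free concentrations.

    Parameters
    ----------
    totals : CompartmentTotals
        Conserved totals of R protomer, catalytic subunit and cAMP.
    params : BindingParams
        Protomer binding model.
    camp_buffered : bool
        If True, treat cAMP as buffered: ``A_free`` is pinned at
        ``A_tot`` and only the C conservation equation is solved.

    Returns
    -------
    EquilibriumState
        Free concentrations satisfy both conservation equations with
        absolute residual below 1e-12 (relative well below 1e-9).
    """
    if totals.R_tot == 0:
        w = protomer_weights(totals.C_tot, totals.A_tot, params)
        return EquilibriumState(totals.C_tot, totals.A_tot, w.mean_c, w.mean_a, w.Z)

    if camp_buffered:
        A_free = totals.A_tot
    elif totals.A_tot == 0:
        A_free = 0.0
    else:
        def a_residual(A: float) -> float:
            C = _solve_c(A, totals, params)
            ma = protomer_weights(C, A, params).mean_a
            return A + totals.R_tot * ma - totals.A_tot

        lo, hi = 0.0, totals.A_tot
        if a_residual(hi) <= 0:
            A_free = hi
        else:
            A_free = brentq(a_residual, lo, hi, xtol=1e-16, rtol=1e-15,
                            maxiter=200)

    C_free = _solve_c(A_free, totals, params)
    w = protomer_weights(C_free, A_free, params)

    res_c = abs(C_free + totals.R_tot * w.mean_c - totals.C_tot)
    if res_c > max(_RES_TOL, 1e-9 * max(totals.C_tot, 1e-12)):
        raise RuntimeError(
            f"conservation residual {res_c:.3e} too large for totals={totals}, "
            f"params={params}")
    return EquilibriumState(C_free, A_free, w.mean_c, w.mean_a, w.Z)


def activity_vs_R(R_x_grid: np.ndarray,
                  basal: CompartmentTotals = DEFAULT_BASAL,
                  rho: float = DEFAULT_RHO,
                  params: BindingParams = DEFAULT_PARAMS,
                  camp_buffered: bool = False) -> ActivityCurve:
    """Free catalytic subunit as a function of translocated R.

    For each grid value ``R_x`` the membrane equilibrium is solved with
    ``R_tot = R_basal + R_x`` and ``C_tot = C_basal + rho * R_x`` (a
    fraction ``rho`` of holoenzyme-bound C travels with the recruited R);
    total cAMP is held fixed.  With the default parameters the curve has
    a unique interior maximum and its high-R tail falls below baseline —
    the prozone signature.
    """
    R_x_grid = np.asarray(R_x_grid, dtype=float)
    if not (0 <= rho <= 1):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if R_x_grid.size == 0:
        return ActivityCurve(R_x_grid, np.empty(0), baseline=np.nan)
    if R_x_grid[0] != 0:
        raise ValueError("R_x grid must start at 0")
    if np.any(np.diff(R_x_grid) < 0) or np.any(R_x_grid < 0):
        raise ValueError("R_x grid must be sorted ascending and non-negative")

    activity = np.empty_like(R_x_grid)
    for i, rx in enumerate(R_x_grid):
        totals = CompartmentTotals(basal.R_tot + rx, basal.C_tot + rho * rx,
                                   basal.A_tot)
        activity[i] = solve_equilibrium(totals, params, camp_buffered).C_free
    return ActivityCurve(R_x_grid, activity, baseline=float(activity[0]))


def activity_at(R_x: float,
                basal: CompartmentTotals = DEFAULT_BASAL,
                rho: float = DEFAULT_RHO,
                params: BindingParams = DEFAULT_PARAMS,
                camp_buffered: bool = False) -> float:
    """Free catalytic subunit at a single translocated-R value."""
    totals = CompartmentTotals(basal.R_tot + R_x, basal.C_tot + rho * R_x,
                               basal.A_tot)
    return solve_equilibrium(totals, params, camp_buffered).C_free


def find_optimum(curve: ActivityCurve):
    """Locate the activity optimum and any below-baseline crossing.

    Returns ``(R_x_opt, activity_opt, crossing)`` where ``crossing`` is the
    first grid value past the optimum at which activity drops strictly
    below baseline, or None if the tail never does.  Ties in the argmax
    break toward smaller R_x.
    """
    if curve.R_x_grid.size == 0:
        raise ValueError("curve is empty")
    i_opt = int(np.argmax(curve.activity))  # first max -> smaller R_x on ties
    below = np.nonzero((curve.activity < curve.baseline)
                       & (np.arange(curve.activity.size) > i_opt))[0]
    crossing = float(curve.R_x_grid[below[0]]) if below.size else None
    return float(curve.R_x_grid[i_opt]), float(curve.activity[i_opt]), crossing


def curve_to_frame(curve: ActivityCurve):
    """ActivityCurve as a pandas DataFrame (columns R_x, activity, baseline)."""
    import pandas as pd

    return pd.DataFrame({
        "R_x": curve.R_x_grid,
        "activity": curve.activity,
        "baseline": curve.baseline,
    })


def with_totals(basal: CompartmentTotals, **kwargs) -> CompartmentTotals:
    """Copy of ``basal`` with selected fields replaced."""
    return replace(basal, **kwargs)
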