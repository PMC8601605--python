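"""Single-cell steady states, linear stability and Hopf threshold location.

The oscillation onset is located as the value of the stimulation strength
V_PLC at which the complex-conjugate eigenvalue pair of the fixed-point
Jacobian crosses the imaginary axis (a Hopf bifurcation).  A real
eigenvalue crossing zero (saddle-node) is deliberately not reported as a
Hopf.  An optional gap-junction "leak" models a stimulated cell whose
neighbours sit clamped at the unstimulated resting state: linear drains
``-Fp*L*(p - p_rest)`` and ``-Fc*L*(c - c_rest)`` with total shared
boundary length ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .core import (
    ModelParameters,
    cell_jacobian_blocks,
    single_cell_rhs,
)

__all__ = [
    "GapJunctionLeak",
    "BifurcationBranch",
    "steady_state",
    "jacobian",
    "hopf_threshold",
    "bifurcation_diagram",
]


@dataclass(frozen=True)
class GapJunctionLeak:
    """Leak of IP3 and Ca2+ into a clamped resting-neighbour reservoir.

    ``boundary_length`` is the total shared boundary with the reservoir;
    the default 6.0 corresponds to a hexagonally packed cell of unit
    diameter.  Permeabilities default to the ``Fp``/``Fc`` of the parameter
    set they are used with when given as None.
    """

    Fp: float | None = None
    Fc: float | None = None
    boundary_length: float = 6.0

    def coefficients(self, params: ModelParameters) -> tuple[float, float]:
        fp = params.Fp if self.Fp is None else self.Fp
        fc = params.Fc if self.Fc is None else self.Fc
        if fp < 0 or fc < 0:
            raise ValueError("leak permeabilities must be >= 0")
        return fp * self.boundary_length, fc * self.boundary_length


def _rest_concentrations(params: ModelParameters) -> tuple[float, float]:
    """(p_rest, c_rest) of an unstimulated, uncoupled cell.

    At V_PLC = 0 the IP3 balance forces p_rest = 0 and c_rest solves the
    scalar leak-vs-SERCA balance k2*(s - c) = V_SERCA*c^2/(c^2+K_SERCA^2).
    """

    def resid(c):
        s = (params.c_tot - c) / params.beta
        return params.k2 * (s - c) - params.V_SERCA * c * c / (
            c * c + params.K_SERCA**2
        )

    return 0.0, brentq(resid, 1e-12, params.c_tot - 1e-12, xtol=1e-14)


def _calcium_residual(c, v_plc, params, a_p, a_c, p_rest, c_rest):
    """Scalar fixed-point residual of dc/dt after eliminating p* and r*."""
    h = c * c / (params.K_PLC**2 + c * c)
    p = (v_plc * h + a_p * p_rest) / (params.k5P + a_p)
    r = params.Kr / (params.Kr + c)
    gate = r * (c / (params.Ka + c)) * (p / (params.Kp + p))
    s = (params.c_tot - c) / params.beta
    release = (params.k1 * gate**3 + params.k2) * (s - c)
    serca = params.V_SERCA * c * c / (c * c + params.K_SERCA**2)
    return release - serca - a_c * (c - c_rest)


def steady_state(
    v_plc: float,
    params: ModelParameters,
    leak: GapJunctionLeak | None = None,
    n_scan: int = 4000,
) -> tuple[float, float, float]:
    """Fixed point (p*, c*, r*) of a single cell at stimulation ``v_plc``.

    The Ca2+ nullcline residual is bracketed on a dense grid over
    (0, c_tot); when the branch folds, the lowest-Ca2+ root (the resting
    branch) is returned.  The returned point satisfies all three rate
    equations to better than 1e-10.
    """
    if v_plc < 0:
        raise ValueError("v_plc must be >= 0")
    a_p = a_c = 0.0
    p_rest = c_rest = 0.0
    if leak is not None:
        a_p, a_c = leak.coefficients(params)
        p_rest, c_rest = _rest_concentrations(params)

    grid = np.linspace(1e-9, params.c_tot * (1 - 1e-9), n_scan)
    vals = _calcium_residual(grid, v_plc, params, a_p, a_c, p_rest, c_rest)
    sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if len(sign_change) == 0:
        raise RuntimeError(
            f"no steady state bracketed for v_plc={v_plc} on c in "
            f"(0, {params.c_tot}); residual range "
            f"[{vals.min():.3g}, {vals.max():.3g}]"
        )
    i = sign_change[0]
    c_star = brentq(
        _calcium_residual, grid[i], grid[i + 1],
        args=(v_plc, params, a_p, a_c, p_rest, c_rest), xtol=1e-15,
    )
    h = c_star**2 / (params.K_PLC**2 + c_star**2)
    p_star = (v_plc * h + a_p * p_rest) / (params.k5P + a_p)
    r_star = params.Kr / (params.Kr + c_star)
    return p_star, c_star, r_star


def jacobian(
    state: tuple[float, float, float],
    v_plc: float,
    params: ModelParameters,
    leak: GapJunctionLeak | None = None,
) -> np.ndarray:
    """Analytic 3x3 Jacobian of (dp/dt, dc/dt, dr/dt) with s eliminated."""
    p, c, r = state
    dfp_dp, dfp_dc, dfc_dp, dfc_dc, dfc_dr, dfr_dc, dfr_dr = cell_jacobian_blocks(
        p, c, r, v_plc, params
    )
    J = np.array(
        [
            [float(dfp_dp), float(dfp_dc), 0.0],
            [float(dfc_dp), float(dfc_dc), float(dfc_dr)],
            [0.0, float(dfr_dc), float(dfr_dr)],
        ]
    )
    if leak is not None:
        a_p, a_c = leak.coefficients(params)
        J[0, 0] -= a_p
        J[1, 1] -= a_c
    return J


def _complex_pair_real(
    v_plc: float, params: ModelParameters, leak: GapJunctionLeak | None
) -> float:
    """Max real part of the complex-conjugate eigenvalue pair at the fixed
    point, or NaN where the pair does not exist (all eigenvalues real)."""
    state = steady_state(v_plc, params, leak)
    eig = np.linalg.eigvals(jacobian(state, v_plc, params, leak))
    pair = eig[np.abs(eig.imag) > 1e-12]
    if len(pair) == 0:
        return np.nan
    return float(pair.real.max())


def hopf_threshold(
    params: ModelParameters,
    leak: GapJunctionLeak | None = None,
    scan: tuple[float, float] = (0.3, 1.5),
    tol: float = 1e-4,
    n_scan: int = 601,
) -> float:
    """First (lowest-V_PLC) Hopf crossing HB1 within ``scan``.

    The complex eigenvalue pair of this model exists only on a narrow
    V_PLC window around the crossing, so the scan grid must be fine
    enough to land inside it; 601 points over the default scan give a
    0.002 step, comfortably inside the ~0.007-wide window at baseline.
    """
    lo, hi = scan
    if not (0 <= lo < hi):
        raise ValueError("scan must satisfy 0 <= lo < hi")
    grid = np.linspace(lo, hi, n_scan)
    vals = np.array([_complex_pair_real(v, params, leak) for v in grid])
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.isfinite(fa) and np.isfinite(fb) and fa < 0 <= fb:
            bracket = (a, b, fa, fb)
            break
    if bracket is None:
        raise RuntimeError(
            f"no Hopf crossing of the complex eigenvalue pair found on "
            f"scan [{lo}, {hi}] with {n_scan} points"
        )
    a, b, fa, fb = bracket
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = _complex_pair_real(mid, params, leak)
        if not np.isfinite(fm):
            raise RuntimeError(
                f"complex eigenvalue pair vanished during bisection at "
                f"v_plc={mid:.6f}"
            )
        if fm < 0:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


@dataclass
class BifurcationBranch:
    """Steady-state branch with stability and stable-cycle extrema.

    Arrays are aligned with ``v_plc``; cycle extrema and period are NaN
    where no sustained oscillation was detected.
    """

    v_plc: np.ndarray
    p_star: np.ndarray
    c_star: np.ndarray
    r_star: np.ndarray
    max_re_eig: np.ndarray
    c_max: np.ndarray = field(default=None)
    c_min: np.ndarray = field(default=None)
    period: np.ndarray = field(default=None)

    @property
    def stable(self) -> np.ndarray:
        return self.max_re_eig < 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_plc": self.v_plc,
                "p_star": self.p_star,
                "c_star": self.c_star,
                "r_star": self.r_star,
                "max_re_eig": self.max_re_eig,
                "c_max": self.c_max,
                "c_min": self.c_min,
                "period": self.period,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def oscillation_extrema(
    v_plc: float,
    params: ModelParameters,
    duration: float = 7200.0,
    transient: float = 1200.0,
    dt: float = 1.0,
) -> tuple[float, float, float]:
    """(c_max, c_min, period) of the attractor of an isolated cell.

    Integrates from the unstimulated resting state, discards the
    transient, and reads the limit cycle off the sampled Ca2+ trace;
    returns NaNs when fewer than three peaks remain (no sustained
    oscillation).
    """
    from .core import resting_state

    rest = resting_state(params)
    t_eval = np.arange(0.0, duration + dt / 2, dt)
    sol = solve_ivp(
        single_cell_rhs,
        (0.0, duration),
        [rest.p, rest.c, rest.r],
        args=(v_plc, params),
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    keep = sol.t >= transient
    c = sol.y[1, keep]
    span = c.max() - c.min()
    peaks, _ = find_peaks(c, prominence=max(0.05 * span, 1e-3))
    if span < 1e-4 or len(peaks) < 3:
        return np.nan, np.nan, np.nan
    t = sol.t[keep]
    period = float(np.mean(np.diff(t[peaks])))
    return float(c.max()), float(c.min()), period


def bifurcation_diagram(
    params: ModelParameters,
    v_plc_grid: np.ndarray,
    leak: GapJunctionLeak | None = None,
    cycle_duration: float = 7200.0,
) -> BifurcationBranch:
    """Steady states, stability, and stable-cycle extrema over a V_PLC grid."""
    grid = np.asarray(v_plc_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("v_plc_grid must be sorted strictly ascending")
    n = len(grid)
    p_s = np.empty(n)
    c_s = np.empty(n)
    r_s = np.empty(n)
    max_re = np.empty(n)
    c_max = np.full(n, np.nan)
    c_min = np.full(n, np.nan)
    period = np.full(n, np.nan)
    for i, v in enumerate(grid):
        state = steady_state(v, params, leak)
        p_s[i], c_s[i], r_s[i] = state
        eig = np.linalg.eigvals(jacobian(state, v, params, leak))
        max_re[i] = float(eig.real.max())
        if max_re[i] > 0:
            c_max[i], c_min[i], period[i] = oscillation_extrema(
                v, params, duration=cycle_duration
            )
    return BifurcationBranch(grid, p_s, c_s, r_s, max_re, c_max, c_min, period)
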