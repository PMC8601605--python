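"""Single-cell IP3/Ca2+/IP3R kinetics and model parameters.

The intracellular model tracks three state variables per cell: cytosolic
IP3 concentration ``p`` (uM), cytosolic Ca2+ concentration ``c`` (uM) and
the fraction ``r`` of IP3 receptors not yet inactivated by Ca2+.  The ER
Ca2+ concentration ``s`` is algebraically slaved to ``c`` through the
conservation relation ``c + beta * s = c_tot`` and is therefore never
integrated, which makes the conservation law exact by construction.

All concentrations are in uM, all times in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ModelParameters",
    "CellState",
    "plc_production",
    "er_calcium",
    "calcium_rhs",
    "ip3_rhs",
    "receptor_rhs",
    "single_cell_rhs",
    "resting_state",
]


@dataclass(frozen=True)
class ModelParameters:
    """Baseline kinetic parameters of the intracellular Ca2+ model.

    Defaults are the published baseline set.  ``receptor_variant`` selects
    the IP3R inactivation equation: ``"modified"`` uses a Ca2+-dependent
    relaxation rate ``(k_tau^4 + c^4) / (tau_max * k_tau^4)``, while
    ``"constant_tau"`` relaxes with the fixed time constant ``tau_r``.

    ``tau_max`` is a time constant and is interpreted in seconds; a rate
    (1/s) would be dimensionally inconsistent with its role as the maximum
    relaxation time of receptor recovery.

    The per-cell stimulation strength V_PLC is deliberately not a field
    here: it is the spatially heterogeneous control parameter, carried by
    :class:`capouch.geometry.VplcField`.
    """

    k5P: float = 0.66        # IP3 dephosphorylation rate, 1/s
    K_PLC: float = 0.2       # half-activation of PLC by Ca2+, uM
    beta: float = 0.185      # effective ER/cytosol volume ratio
    V_SERCA: float = 0.9     # maximum SERCA pump rate, uM/s
    K_SERCA: float = 0.1     # SERCA half-activation, uM
    k1: float = 1.11         # maximum IP3R release rate, 1/s
    k2: float = 0.0203       # ER leak rate, 1/s
    Ka: float = 0.08         # Ca2+ binding to IP3R activating site, uM
    Kr: float = 0.4          # Ca2+ binding to IP3R inactivating site, uM
    Kp: float = 0.13         # IP3 binding to IP3R, uM
    tau_max: float = 800.0   # maximum IP3R inactivation time constant, s
    k_tau: float = 1.5       # Ca2+ scale of IP3R inactivation rate, uM
    Fp: float = 0.005        # GJ permeability for IP3, per unit boundary
    Fc: float = 0.0005       # GJ permeability for Ca2+, per unit boundary
    c_tot: float = 2.0       # total Ca2+ (cytosol + beta-scaled ER), uM
    receptor_variant: str = "modified"
    tau_r: float | None = None  # only used with receptor_variant="constant_tau"

    _POSITIVE = (
        "k5P", "K_PLC", "beta", "V_SERCA", "K_SERCA", "k1", "k2",
        "Ka", "Kr", "Kp", "tau_max", "k_tau", "c_tot",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"parameter {name} must be > 0, got {value!r}")
        for name in ("Fp", "Fc"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta!r}")
        if self.receptor_variant not in ("modified", "constant_tau"):
            raise ValueError(
                f"unknown receptor_variant {self.receptor_variant!r}; "
                "expected 'modified' or 'constant_tau'"
            )
        if self.receptor_variant == "constant_tau":
            if self.tau_r is None or not (self.tau_r > 0):
                raise ValueError("receptor_variant='constant_tau' requires tau_r > 0")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["tau_r"] is None:
            del d["tau_r"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class CellState:
    """State of one cell: IP3 ``p`` (uM), Ca2+ ``c`` (uM), available IP3R
    fraction ``r`` (dimensionless)."""

    p: float
    c: float
    r: float

    def validate(self, params: ModelParameters) -> "CellState":
        if self.p < 0:
            raise ValueError(f"p must be >= 0, got {self.p}")
        if not 0 <= self.c <= params.c_tot:
            raise ValueError(f"c must lie in [0, c_tot={params.c_tot}], got {self.c}")
        if not 0 <= self.r <= 1:
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        return self


def plc_production(c: ArrayLike, v_plc: ArrayLike, params: ModelParameters) -> ArrayLike:
    """Ca2+-activated IP3 production rate, ``v_plc * c^2 / (K_PLC^2 + c^2)``.

    Hill-type activation of PLC by cytosolic Ca2+; ``v_plc`` is the maximal
    production rate (uM/s), the stimulation-strength control parameter.
    """
    c = np.asarray(c, dtype=float)
    v = np.asarray(v_plc, dtype=float)
    if np.any(c < 0):
        raise ValueError("Ca2+ concentration must be >= 0")
    if np.any(v < 0):
        raise ValueError("v_plc must be >= 0")
    out = v * c * c / (params.K_PLC**2 + c * c)
    return float(out) if out.ndim == 0 else out


def er_calcium(c: ArrayLike, params: ModelParameters) -> ArrayLike:
    """ER Ca2+ concentration ``s = (c_tot - c) / beta`` (uM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > params.c_tot):
        raise ValueError("c must lie in [0, c_tot]")
    out = (params.c_tot - c) / params.beta
    return float(out) if out.ndim == 0 else out


def _release_gate(p: ArrayLike, c: ArrayLike, r: ArrayLike, params: ModelParameters):
    """Open probability factor of the IP3R, ``r * c/(Ka+c) * p/(Kp+p)``."""
    return r * (c / (params.Ka + c)) * (p / (params.Kp + p))


def calcium_rhs(state: CellState, jc: float, params: ModelParameters) -> float:
    """dc/dt (uM/s): IP3R release + ER leak - SERCA uptake + GJ flux ``jc``."""
    state.validate(params)
    return float(_calcium_rate(state.p, state.c, state.r, jc, params))


def _calcium_rate(p, c, r, jc, params: ModelParameters):
    s = (params.c_tot - c) / params.beta
    gate = _release_gate(p, c, r, params)
    release = (params.k1 * gate**3 + params.k2) * (s - c)
    serca = params.V_SERCA * c * c / (c * c + params.K_SERCA**2)
    return jc + release - serca


def ip3_rhs(state: CellState, v_plc: float, jp: float, params: ModelParameters) -> float:
    """dp/dt (uM/s): PLC production - first-order degradation + GJ flux ``jp``."""
    state.validate(params)
    return float(jp + plc_production(state.c, v_plc, params) - params.k5P * state.p)


def receptor_rhs(state: CellState, params: ModelParameters) -> float:
    """dr/dt (1/s): relaxation of the available IP3R fraction towards its
    Ca2+-dependent equilibrium ``Kr / (Kr + c)``.

    The ``modified`` variant accelerates relaxation at high Ca2+ by the
    factor ``(k_tau^4 + c^4) / k_tau^4``; the ``constant_tau`` variant uses
    the fixed time constant ``tau_r``.
    """
    state.validate(params)
    return float(_receptor_rate(state.c, state.r, params))


def _receptor_rate(c, r, params: ModelParameters):
    drive = 1.0 - r * (params.Kr + c) / params.Kr
    if params.receptor_variant == "modified":
        rate = (params.k_tau**4 + np.asarray(c, dtype=float) ** 4) / (
            params.tau_max * params.k_tau**4
        )
    else:
        rate = 1.0 / params.tau_r
    return rate * drive


def single_cell_rhs(t: float, y: np.ndarray, v_plc: float,
                    params: ModelParameters) -> np.ndarray:
    """RHS of an isolated cell, ``y = (p, c, r)``, for use with ODE solvers."""
    p, c, r = y
    dp = v_plc * c * c / (params.K_PLC**2 + c * c) - params.k5P * p
    dc = _calcium_rate(p, c, r, 0.0, params)
    dr = _receptor_rate(c, r, params)
    return np.array([dp, dc, dr])


def resting_state(params: ModelParameters, v_plc: float = 0.0) -> CellState:
    """Fixed point of an isolated cell (the resting state at ``v_plc = 0``).

    Delegates to the bifurcation machinery; provided here because the
    coupled simulator uses it as the default initial condition.
    """
    from .bifurcation import steady_state

    p, c, r = steady_state(v_plc, params)
    return CellState(p=p, c=c, r=r)


def cell_jacobian_blocks(p, c, r, v_plc, params: ModelParameters):
    """Partial derivatives of the reaction terms, vectorised over cells.

    Returns the seven non-trivially-zero entries of the per-cell 3x3
    reaction Jacobian (with s eliminated), in the order
    (dfp_dp, dfp_dc, dfc_dp, dfc_dc, dfc_dr, dfr_dc, dfr_dr).
    GJ coupling terms are not included.
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    r = np.asarray(r, dtype=float)
    Ka, Kp, Kr = params.Ka, params.Kp, params.Kr
    s_minus_c = (params.c_tot - c) / params.beta - c
    gate = _release_gate(p, c, r, params)
    dg_dp = r * (c / (Ka + c)) * Kp / (Kp + p) ** 2
    dg_dc = r * (p / (Kp + p)) * Ka / (Ka + c) ** 2
    dg_dr = (c / (Ka + c)) * (p / (Kp + p))
    k1 = params.k1
    release_coeff = k1 * gate**3 + params.k2
    g2 = 3.0 * k1 * gate**2

    dfp_dp = -params.k5P * np.ones_like(p)
    dfp_dc = np.asarray(v_plc, dtype=float) * 2 * c * params.K_PLC**2 / (
        params.K_PLC**2 + c * c
    ) ** 2
    dfc_dp = g2 * dg_dp * s_minus_c
    dfc_dc = (
        g2 * dg_dc * s_minus_c
        + release_coeff * (-1.0 / params.beta - 1.0)
        - params.V_SERCA * 2 * c * params.K_SERCA**2 / (c * c + params.K_SERCA**2) ** 2
    )
    dfc_dr = g2 * dg_dr * s_minus_c
    drive = 1.0 - r * (Kr + c) / Kr
    if params.receptor_variant == "modified":
        rate = (params.k_tau**4 + c**4) / (params.tau_max * params.k_tau**4)
        drate_dc = 4 * c**3 / (params.tau_max * params.k_tau**4)
    else:
        rate = 1.0 / params.tau_r + np.zeros_like(c)
        drate_dc = np.zeros_like(c)
    dfr_dc = drate_dc * drive - rate * r / Kr
    dfr_dr = -rate * (Kr + c) / Kr
    return dfp_dp, dfp_dc, dfc_dp, dfc_dc, dfc_dr, dfr_dc, dfr_dr
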