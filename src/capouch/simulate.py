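"""Tissue-scale coupled simulation and the published scenario runners.

Each cell contributes three ODEs (p, c, r); cells exchange IP3 and Ca2+
across gap junctions in discrete-Laplacian form

    J_i = F * sum_{j in N_i} l_ij * (x_j - x_i),

which vanishes at uniform concentration and conserves the tissue total
exactly.  The stacked 3N system is integrated with an implicit
stiff-capable solver using the analytic sparse Jacobian assembled from
the per-cell reaction blocks plus the coupling Laplacian.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .core import ModelParameters, cell_jacobian_blocks
from .geometry import TissueGeometry, VplcField, assign_vplc, generate_tissue

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TissueTrajectory",
    "coupling_matrix",
    "gj_flux",
    "simulate",
    "pattern_scenario",
    "gj_block_scenario",
    "scaling_scenario",
    "sensitivity_sweep",
    "PATTERN_STANDBY_RANGES",
    "default_initiator_count",
]

#: Standby-cell V_PLC ranges (uM/s) that produce each signaling class.
PATTERN_STANDBY_RANGES = {
    "spikes": (0.1, 0.5),
    "ICT": (0.25, 0.60),
    "ICW": (0.4, 0.8),
    "fluttering": (1.4, 1.5),
}

#: Initiator V_PLC range for the four pattern scenarios.
PATTERN_INITIATOR_RANGE = (1.4, 1.5)

#: Equilibration discarded before the reported hour in unstimulated-tissue
#: runs (s).  The gap-junction block experiment images tissue sitting in
#: basal media, already at its dynamical steady state, so the uniform
#: resting start must be allowed to relax before observation begins.  The
#: stimulation scenarios, by contrast, emulate acute agonist addition at
#: t = 0 and deliberately start from the unstimulated resting state with
#: no burn-in: the evoked response is the signal.
EQUILIBRATION_BURN_IN = 1200.0


def _equilibrated_config(config):
    return config if config is not None else SimulationConfig(
        burn_in=EQUILIBRATION_BURN_IN
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings: 1 h of simulated time sampled every 10 s by
    default, matching the cadence of the live-imaging experiments the
    simulations emulate."""

    duration: float = 3600.0
    sample_interval: float = 10.0
    rtol: float = 1e-6
    atol: float = 1e-9
    ic_mode: str = "resting"          # "resting" or "custom"
    perturb_c: float = 0.0            # fractional seeded jitter on initial c
    burn_in: float = 0.0              # equilibration time discarded before t=0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if not 0 < self.sample_interval <= self.duration:
            raise ValueError("sample interval must lie in (0, duration]")
        if self.ic_mode not in ("resting", "custom"):
            raise ValueError("ic_mode must be 'resting' or 'custom'")

    def sample_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.sample_interval / 2,
                         self.sample_interval)


@dataclass
class TissueTrajectory:
    """Sampled (p, c, r) time series for every cell plus provenance."""

    t: np.ndarray                  # (T,)
    p: np.ndarray                  # (T, N)
    c: np.ndarray                  # (T, N)
    r: np.ndarray                  # (T, N)
    tissue: TissueGeometry
    vplc: VplcField
    params: ModelParameters
    config: SimulationConfig

    def __post_init__(self):
        T, N = self.c.shape
        if self.p.shape != (T, N) or self.r.shape != (T, N) or len(self.t) != T:
            raise ValueError("inconsistent trajectory array shapes")

    @property
    def n_cells(self) -> int:
        return self.c.shape[1]

    def er_calcium(self) -> np.ndarray:
        return (self.params.c_tot - self.c) / self.params.beta

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            g = fh.create_group("traj")
            for name in ("t", "p", "c", "r"):
                g.create_dataset(name, data=getattr(self, name))
            geo = fh.create_group("geometry")
            geo.create_dataset("centroids", data=self.tissue.centroids)
            geo.create_dataset("areas", data=self.tissue.areas)
            geo.create_dataset("edges", data=self.tissue.edges)
            geo.create_dataset("edge_lengths", data=self.tissue.edge_lengths)
            polys = self.tissue.polygons
            geo.create_dataset("polygon_vertices", data=np.vstack(polys))
            geo.create_dataset(
                "polygon_offsets",
                data=np.cumsum([0] + [len(p) for p in polys]),
            )
            vp = fh.create_group("vplc")
            vp.create_dataset("values", data=self.vplc.values)
            vp.create_dataset("initiator_mask", data=self.vplc.initiator_mask)
            fh.attrs["params"] = json.dumps(self.params.to_dict())
            fh.attrs["config"] = json.dumps(asdict(self.config))

    @classmethod
    def load_h5(cls, path) -> "TissueTrajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            verts = fh["geometry/polygon_vertices"][()]
            offs = fh["geometry/polygon_offsets"][()]
            polygons = [verts[a:b] for a, b in zip(offs[:-1], offs[1:])]
            tissue = TissueGeometry(
                centroids=fh["geometry/centroids"][()],
                polygons=polygons,
                areas=fh["geometry/areas"][()],
                edges=fh["geometry/edges"][()],
                edge_lengths=fh["geometry/edge_lengths"][()],
            )
            vplc = VplcField(
                values=fh["vplc/values"][()],
                initiator_mask=fh["vplc/initiator_mask"][()],
            )
            params = ModelParameters.from_dict(json.loads(fh.attrs["params"]))
            config = SimulationConfig(**json.loads(fh.attrs["config"]))
            return cls(
                t=fh["traj/t"][()], p=fh["traj/p"][()], c=fh["traj/c"][()],
                r=fh["traj/r"][()], tissue=tissue, vplc=vplc,
                params=params, config=config,
            )


def coupling_matrix(tissue: TissueGeometry) -> sp.csr_matrix:
    """Boundary-length-weighted graph Laplacian operator ``W - D``.

    ``(W - D) @ x`` gives, per cell, ``sum_j l_ij * (x_j - x_i)``; rows sum
    to zero, so uniform fields produce zero flux and column sums make the
    exchange conservative.
    """
    n = tissue.n_cells
    if len(tissue.edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = tissue.edges.T
    l = tissue.edge_lengths
    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    data = np.concatenate([l, l])
    W = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    D = sp.diags(np.asarray(W.sum(axis=1)).ravel())
    return (W - D).tocsr()


def gj_flux(values: np.ndarray, tissue: TissueGeometry, F: float) -> np.ndarray:
    """Per-cell gap-junction flux ``F * sum_j l_ij * (x_j - x_i)``."""
    if F < 0:
        raise ValueError("permeability F must be >= 0")
    values = np.asarray(values, dtype=float)
    if values.shape != (tissue.n_cells,):
        raise ValueError("values must have one entry per cell")
    return F * (coupling_matrix(tissue) @ values)


class _TissueSystem:
    """Stacked RHS and analytic sparse Jacobian for the coupled tissue."""

    def __init__(self, tissue, vplc_values, params, reactions=True):
        self.n = tissue.n_cells
        self.L = coupling_matrix(tissue)
        self.v = np.asarray(vplc_values, dtype=float)
        self.params = params
        self.reactions = reactions

    def rhs(self, t, y):
        P = self.params
        n = self.n
        p, c, r = y[:n], y[n:2 * n], y[2 * n:]
        dp = P.Fp * (self.L @ p)
        dc = P.Fc * (self.L @ c)
        if not self.reactions:
            return np.concatenate([dp, dc, np.zeros(n)])
        h = c * c / (P.K_PLC**2 + c * c)
        dp += self.v * h - P.k5P * p
        s_minus_c = (P.c_tot - c) / P.beta - c
        gate = r * (c / (P.Ka + c)) * (p / (P.Kp + p))
        dc += (P.k1 * gate**3 + P.k2) * s_minus_c
        dc -= P.V_SERCA * c * c / (c * c + P.K_SERCA**2)
        if P.receptor_variant == "modified":
            rate = (P.k_tau**4 + c**4) / (P.tau_max * P.k_tau**4)
        else:
            rate = 1.0 / P.tau_r
        dr = rate * (1.0 - r * (P.Kr + c) / P.Kr)
        return np.concatenate([dp, dc, dr])

    def jac(self, t, y):
        P = self.params
        n = self.n
        p, c, r = y[:n], y[n:2 * n], y[2 * n:]
        if self.reactions:
            fpp, fpc, fcp, fcc, fcr, frc, frr = cell_jacobian_blocks(
                p, c, r, self.v, P
            )
        else:
            z = np.zeros(n)
            fpp = fpc = fcp = fcc = fcr = frc = frr = z
        return sp.bmat(
            [
                [P.Fp * self.L + sp.diags(fpp), sp.diags(fpc), None],
                [sp.diags(fcp), P.Fc * self.L + sp.diags(fcc), sp.diags(fcr)],
                [None, sp.diags(frc), sp.diags(frr)],
            ],
            format="csc",
        )


def _initial_state(tissue, params, config):
    from .core import resting_state

    rest = resting_state(params)
    n = tissue.n_cells
    y0 = np.concatenate(
        [np.full(n, rest.p), np.full(n, rest.c), np.full(n, rest.r)]
    )
    if config.perturb_c:
        rng = np.random.default_rng(config.seed)
        y0[n:2 * n] *= 1.0 + config.perturb_c * rng.uniform(-1, 1, n)
    return y0


def simulate(
    tissue: TissueGeometry,
    vplc_field: VplcField,
    params: ModelParameters | None = None,
    config: SimulationConfig | None = None,
    y0: np.ndarray | None = None,
    reactions: bool = True,
) -> TissueTrajectory:
    """Integrate the coupled tissue and sample at the configured interval.

    ``y0`` overrides the initial condition (stacked ``[p, c, r]``) when
    ``config.ic_mode == "custom"``.  ``reactions=False`` integrates pure
    gap-junction diffusion, used to verify exchange conservation.
    """
    params = params or ModelParameters()
    config = config or SimulationConfig()
    if len(vplc_field.values) != tissue.n_cells:
        raise ValueError("vplc field size does not match tissue")
    if config.ic_mode == "custom":
        if y0 is None:
            raise ValueError("ic_mode='custom' requires y0")
        y0 = np.asarray(y0, dtype=float)
    else:
        y0 = _initial_state(tissue, params, config)
    system = _TissueSystem(tissue, vplc_field.values, params, reactions)
    sol = solve_ivp(
        system.rhs,
        (0.0, config.burn_in + config.duration),
        y0,
        method="BDF",
        jac=system.jac,
        t_eval=config.burn_in + config.sample_times(),
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(
            f"tissue integration failed at t={t_fail:.1f} s: {sol.message}"
        )
    n = tissue.n_cells
    return TissueTrajectory(
        t=sol.t - config.burn_in,
        p=sol.y[:n].T.copy(),
        c=sol.y[n:2 * n].T.copy(),
        r=sol.y[2 * n:].T.copy(),
        tissue=tissue,
        vplc=vplc_field,
        params=params,
        config=config,
    )


def default_initiator_count(n_cells: int) -> int:
    """A small initiator population: 2% of the tissue, at least one cell."""
    return max(1, round(0.02 * n_cells))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def pattern_scenario(
    class_name: str,
    n_cells: int = 200,
    seed: int = 0,
    params: ModelParameters | None = None,
    config: SimulationConfig | None = None,
) -> TissueTrajectory:
    """Run one of the four signaling-class scenarios.

    Standby V_PLC is uniform on the class-specific range; initiators are
    uniform on [1.4, 1.5].  In the fluttering scenario the standby range
    coincides with the initiator range, so every cell is effectively an
    initiator.
    """
    if class_name not in PATTERN_STANDBY_RANGES:
        raise ValueError(
            f"unknown class {class_name!r}; expected one of "
            f"{sorted(PATTERN_STANDBY_RANGES)}"
        )
    geo_seed, vplc_seed = _spawn_seeds(seed, 2)
    tissue = generate_tissue(n_cells, seed=geo_seed)
    field = assign_vplc(
        tissue,
        default_initiator_count(n_cells),
        PATTERN_INITIATOR_RANGE,
        PATTERN_STANDBY_RANGES[class_name],
        seed=vplc_seed,
    )
    return simulate(tissue, field, params, config)


def gj_block_scenario(
    n_cells: int = 200,
    blocked: bool = False,
    seed: int = 0,
    n_initiators: int | None = None,
    initiator_vplc: float = 0.774,
    config: SimulationConfig | None = None,
) -> TissueTrajectory:
    """Initiators pinned at the single-cell Hopf threshold, standby on
    [0.1, 0.5]; gap junctions at baseline permeability or fully blocked."""
    geo_seed, vplc_seed = _spawn_seeds(seed, 2)
    tissue = generate_tissue(n_cells, seed=geo_seed)
    if n_initiators is None:
        n_initiators = default_initiator_count(n_cells)
    field = assign_vplc(
        tissue, n_initiators,
        (initiator_vplc, initiator_vplc), (0.1, 0.5), seed=vplc_seed,
    )
    params = ModelParameters()
    if blocked:
        params = params.replace(Fp=0.0, Fc=0.0)
    return simulate(tissue, field, params, _equilibrated_config(config))


def initiator_count_scaling(n_cells: int) -> int:
    """Initiator count under the developmental power law 8000 * N^-0.8,
    rounded to the nearest integer, floored at 1 and clamped to N."""
    n_init = max(1, round(8000.0 * n_cells**-0.8))
    if n_init > n_cells:
        log.warning(
            "initiator scaling gives %d initiators for %d cells; clamping",
            n_init, n_cells,
        )
        n_init = n_cells
    return n_init


def permeability_scaling(n_cells: int) -> tuple[float, float]:
    """(Fp, Fc) under the developmental power law Fp = 800 * N^-1.8 with
    Fc = 0.1 * Fp."""
    fp = 800.0 * n_cells**-1.8
    return fp, 0.1 * fp


def scaling_scenario(
    mode: str,
    n_cells_list,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> list[TissueTrajectory]:
    """Developmental scaling runs over increasing tissue sizes.

    ``initiator_scaling``: initiator count follows 8000 * N^-0.8 with
    baseline permeability.  ``permeability_scaling``: Fp = 800 * N^-1.8,
    Fc = 0.1 * Fp, with a constant 65 initiators (clamped to N).  Both
    modes fix standby V_PLC at 0.40 and draw initiators on [1.3, 1.5].
    """
    if mode not in ("initiator_scaling", "permeability_scaling"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if any(n < 1 for n in n_cells_list):
        raise ValueError("all tissue sizes must be >= 1")
    seeds = _spawn_seeds(seed, 2 * len(n_cells_list))
    out = []
    for k, n_cells in enumerate(n_cells_list):
        params = ModelParameters()
        if mode == "initiator_scaling":
            n_init = initiator_count_scaling(n_cells)
        else:
            fp, fc = permeability_scaling(n_cells)
            params = params.replace(Fp=fp, Fc=fc)
            n_init = 65
            if n_init > n_cells:
                log.warning("clamping 65 initiators to %d cells", n_cells)
                n_init = n_cells
        tissue = generate_tissue(n_cells, seed=seeds[2 * k])
        field = assign_vplc(
            tissue, n_init, (1.3, 1.5), (0.40, 0.40), seed=seeds[2 * k + 1]
        )
        out.append(simulate(tissue, field, params, config))
    return out


#: Sweep baseline: an intercellular-wave tissue with standby V_PLC on
#: [0.7, 1.0], reused (frozen) across every sweep point.
SWEEP_STANDBY_RANGE = (0.7, 1.0)

_SWEEPABLE = {
    "k5P", "K_PLC", "beta", "V_SERCA", "K_SERCA", "k1", "k2", "Ka", "Kr",
    "Kp", "tau_max", "k_tau", "Fp", "Fc", "c_tot", "Fp_Fc_joint",
}


def sensitivity_sweep(
    parameter_name: str,
    percentages,
    n_cells: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
):
    """One-parameter sensitivity sweep on a frozen ICW baseline tissue.

    Each percentage scales the named parameter relative to its baseline
    (``Fp_Fc_joint`` co-scales both permeabilities); the same tissue and
    V_PLC field are reused at every point.  Returns a pandas DataFrame of
    per-point summary metrics and the list of trajectories.
    """
    import pandas as pd

    from .quantify import analyze_trajectory

    if parameter_name not in _SWEEPABLE:
        raise ValueError(f"unknown parameter {parameter_name!r}")
    if any(pct <= 0 for pct in percentages):
        raise ValueError("percentages must be > 0")
    geo_seed, vplc_seed = _spawn_seeds(seed, 2)
    tissue = generate_tissue(n_cells, seed=geo_seed)
    field = assign_vplc(
        tissue, default_initiator_count(n_cells),
        PATTERN_INITIATOR_RANGE, SWEEP_STANDBY_RANGE, seed=vplc_seed,
    )
    base = ModelParameters()
    rows = []
    trajectories = []
    for pct in percentages:
        scale = pct / 100.0
        if parameter_name == "Fp_Fc_joint":
            params = base.replace(Fp=base.Fp * scale, Fc=base.Fc * scale)
            value = base.Fp * scale
        else:
            value = getattr(base, parameter_name) * scale
            params = base.replace(**{parameter_name: value})
        traj = simulate(tissue, field, params, config)
        report = analyze_trajectory(traj)
        trajectories.append(traj)
        rows.append(
            {
                "parameter": parameter_name,
                "percent": pct,
                "value": value,
                "mean_frequency_hz": report.mean_frequency,
                "mean_whm_s": report.mean_whm,
                "max_event_span_cells": report.max_event_span,
                "pattern_class": report.pattern_class,
                "integrated_activity": report.integrated_activity,
            }
        )
    return pd.DataFrame(rows), trajectories
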