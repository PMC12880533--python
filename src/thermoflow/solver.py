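"""Steady and transient conjugate heat transport on the structured grid.

Finite-volume discretization: central-difference diffusion with harmonic-mean
face conductivities, first-order upwind advection in the fluid, uniform
volumetric heating over the actuator cells.  Boundary conditions follow the
benchtop configuration: insulated lateral faces, fixed bottom temperature,
convective (Robin) exchange at the exposed top of the air region, fixed inlet
temperature with advective inflow, and zero-diffusive-flux outflow at the
channel exit.

The linear system is solved by sparse LU for moderate grids and by
ILU-preconditioned BiCGSTAB for large ones; the relative residual is checked
against ``RESIDUAL_TOL`` in both cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import MATERIAL_CODES, SimulationGrid
from .scenario import (
    AmbientConditions,
    FlowCondition,
    MaterialProperties,
    Scenario,
    SensorLayout,
)

__all__ = [
    "ThermalField",
    "SingularSystemError",
    "DivergenceError",
    "solve_steady",
    "solve_transient",
    "solve_scenario",
    "probe_temperature",
    "sensor_positions",
    "sensor_readings",
    "energy_balance_residual",
    "normalized_reading",
    "power_density",
    "CHANNEL_NAMES",
]

RESIDUAL_TOL = 1e-8

#: Fixed six-channel order used everywhere downstream.
CHANNEL_NAMES = (
    "t_top_up",
    "t_top_dn",
    "t_top_ref",
    "t_bot_up",
    "t_bot_dn",
    "t_bot_ref",
)


class SingularSystemError(RuntimeError):
    """The assembled system has no Dirichlet/Robin condition anchoring it."""


class DivergenceError(RuntimeError):
    """Non-finite values appeared during transient stepping."""


@dataclass
class ThermalField:
    """Temperature field (deg C) on a SimulationGrid, cell-centered."""

    temperature: np.ndarray  # (nx, ny, nz)
    grid: SimulationGrid
    steady: bool = True
    time: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.temperature)):
            raise DivergenceError("non-finite temperatures in field")


def _cell_property(grid: SimulationGrid, materials: dict[str, MaterialProperties],
                   attr: str) -> np.ndarray:
    out = np.empty(grid.shape)
    for name, code in MATERIAL_CODES.items():
        mask = grid.material == code
        if mask.any():
            if name not in materials:
                raise KeyError(f"material map missing entry for {name!r}")
            out[mask] = getattr(materials[name], attr)
    return out


def _assemble(
    grid: SimulationGrid,
    materials: dict[str, MaterialProperties],
    ambient: AmbientConditions,
    actuator_power_mw: float,
):
    """Build A, b with A T = b the steady balance; A@T - b is net power in (W)."""
    sp_m = grid.spacing * 1e-3
    area = sp_m**2
    nx, ny, nz = grid.shape
    n = grid.n_cells
    kcell = _cell_property(grid, materials, "thermal_conductivity")
    rc = _cell_property(grid, materials, "volumetric_heat_capacity")
    idx3 = np.arange(n).reshape(grid.shape)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n)
    b = np.zeros(n)

    def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    # interior diffusion, all three axes
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        k1, k2 = kcell[tuple(lo)], kcell[tuple(hi)]
        cf = (2.0 * k1 * k2 / (k1 + k2)) * sp_m  # W/K
        i1, i2 = idx3[tuple(lo)], idx3[tuple(hi)]
        add(i1, i2, cf)
        add(i2, i1, cf)
        np.add.at(diag, i1.ravel(), -cf.ravel())
        np.add.at(diag, i2.ravel(), -cf.ravel())

    # upwind advection across interior x-faces (fluid-fluid only)
    fluid = grid.fluid_mask()
    u = grid.velocity_x * 1e-3  # m/s
    both = fluid[:-1] & fluid[1:]
    uf = np.where(both, 0.5 * (u[:-1] + u[1:]), 0.0)
    mflux = rc[:-1] * np.abs(uf) * area  # W/K, rc identical across fluid faces
    i1, i2 = idx3[:-1], idx3[1:]
    pos = uf > 0
    neg = uf < 0
    if pos.any():
        m = np.where(pos, mflux, 0.0)
        add(i2, i1, m)  # downstream cell gains m*T_up
        np.add.at(diag, i1.ravel(), -m.ravel())
    if neg.any():
        m = np.where(neg, mflux, 0.0)
        add(i1, i2, m)
        np.add.at(diag, i2.ravel(), -m.ravel())

    anchored = False

    # bottom surface: fixed temperature (half-cell conduction)
    if ambient.bottom_surface_temperature is not None:
        cb = 2.0 * kcell[:, :, 0] * sp_m
        ib = idx3[:, :, 0].ravel()
        np.add.at(diag, ib, -cb.ravel())
        np.add.at(b, ib, -cb.ravel() * ambient.bottom_surface_temperature)
        anchored = True

    # top of the air region: Robin exchange with ambient
    h = ambient.convective_coefficient
    if h > 0:
        kt = kcell[:, :, -1]
        U = area / (1.0 / h + (grid.spacing * 5e-4) / kt)
        it = idx3[:, :, -1].ravel()
        np.add.at(diag, it, -U.ravel())
        np.add.at(b, it, -U.ravel() * ambient.ambient_temperature)
        anchored = True

    # channel inlet (x min): fixed fluid temperature + advective inflow.
    # The inlet condition is upwind-consistent: it applies only when fluid
    # actually enters, so a zero-flow channel has symmetric (insulated) ends.
    fin = fluid[0] & (u[0] > 0)
    if fin.any():
        ii = idx3[0][fin]
        cin = 2.0 * kcell[0][fin] * sp_m
        madv = rc[0][fin] * u[0][fin] * area
        np.add.at(diag, ii, -(cin))
        np.add.at(b, ii, -(cin) * ambient.inlet_fluid_temperature)
        # inflow enthalpy at T_in, matching outflow loss at the exit
        np.add.at(b, ii, -madv * ambient.inlet_fluid_temperature)
        anchored = True

    # channel outlet (x max): advective outflow, zero diffusive flux
    fout = fluid[-1]
    if fout.any():
        io = idx3[-1][fout]
        mout = rc[-1][fout] * np.abs(u[-1][fout]) * area
        np.add.at(diag, io, -mout)

    if not anchored:
        raise SingularSystemError(
            "no Dirichlet or Robin boundary anchors the temperature level: "
            "set a bottom temperature or a positive convective coefficient"
        )

    # uniform heat source over the actuator (copper) cells
    if actuator_power_mw > 0:
        cu = grid.material == MATERIAL_CODES["copper"]
        ncu = int(cu.sum())
        if ncu == 0:
            raise ValueError("actuator power requested but no copper cells in grid")
        b[idx3[cu].ravel()] -= actuator_power_mw * 1e-3 / ncu

    add(np.arange(n), np.arange(n), diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, b


def _linear_solve(A: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    Ac = A.tocsc()
    try:
        ilu = spla.spilu(Ac, drop_tol=1e-5, fill_factor=10.0)
        M = spla.LinearOperator(A.shape, ilu.solve)
        T, info = spla.bicgstab(A, b, M=M, rtol=1e-12, atol=0.0, maxiter=2000)
        if info != 0:
            raise RuntimeError(f"bicgstab info={info}")
    except RuntimeError:
        # fall back to a sparse direct factorization
        T = spla.splu(Ac, permc_spec="MMD_AT_PLUS_A").solve(b)
    res = np.linalg.norm(A @ T - b) / max(np.linalg.norm(b), 1e-30)
    if res > RESIDUAL_TOL:
        raise SingularSystemError(f"linear residual {res:.2e} above tolerance")
    return T


def solve_steady(
    grid: SimulationGrid,
    materials: dict[str, MaterialProperties],
    ambient: AmbientConditions,
    flow: FlowCondition | None = None,
    actuator_power_mw: float = 0.0,
) -> ThermalField:
    """Solve the steady conjugate conduction/advection problem.

    If ``flow`` is given the grid's velocity field is rebuilt for it;
    otherwise the velocities already stored on the grid are used.
    """
    if flow is not None:
        grid = grid.with_velocity(flow.mean_speed, "plug") if flow.profile == "plug" \
            else _parabolic(grid, flow)
    A, b = _assemble(grid, materials, ambient, actuator_power_mw)
    T = _linear_solve(A, b)
    return ThermalField(T.reshape(grid.shape), grid, steady=True)


def _parabolic(grid: SimulationGrid, flow: FlowCondition) -> SimulationGrid:
    fluid = grid.fluid_mask()
    zc = grid.cell_centers(2)
    yc = grid.cell_centers(1)
    # infer axis center and radius from the voxelized channel
    jj, kk = np.nonzero(fluid[fluid.shape[0] // 2])
    cy = float(yc[jj].mean())
    czc = float(zc[kk].mean())
    r = max(
        float(np.max(np.hypot(yc[jj] - cy, zc[kk] - czc))) + grid.spacing / 2, 1e-9
    )
    return grid.with_velocity(flow.mean_speed, "parabolic", czc, r)


def solve_transient(
    grid: SimulationGrid,
    materials: dict[str, MaterialProperties],
    ambient: AmbientConditions,
    flow_profile: Sequence[tuple[float, FlowCondition]],
    actuator_power_mw: float,
    duration: float,
    dt: float,
    initial_temperature: float = 25.0,
    record_every: int = 1,
) -> list[ThermalField]:
    """Implicit-Euler time stepping from a uniform initial field.

    ``flow_profile`` is a piecewise-constant schedule of (start_time, flow)
    pairs sorted by start time; the first entry must start at t = 0.  The
    system matrix is refactorized only when the flow level changes.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    if not flow_profile or flow_profile[0][0] > 0:
        raise ValueError("flow profile must start at t = 0")

    sp_m = grid.spacing * 1e-3
    rc = _cell_property(grid, materials, "volumetric_heat_capacity")
    cap = (rc * sp_m**3 / dt).ravel()  # W/K per cell

    T = np.full(grid.n_cells, float(initial_temperature))
    fields: list[ThermalField] = []
    nsteps = int(round(duration / dt))
    times = [t0 for t0, _ in flow_profile]
    lu = None
    b = None
    current_seg = -1
    for step in range(1, nsteps + 1):
        t = step * dt
        seg = int(np.searchsorted(times, t - dt / 2, side="right") - 1)
        if seg != current_seg:
            current_seg = seg
            g = grid.with_velocity(flow_profile[seg][1].mean_speed,
                                   flow_profile[seg][1].profile)
            A, b = _assemble(g, materials, ambient, actuator_power_mw)
            Aimp = (A - sp.diags(cap)).tocsc()
            lu = spla.splu(Aimp, permc_spec="MMD_AT_PLUS_A")
        T = lu.solve(b - cap * T)
        if not np.all(np.isfinite(T)):
            raise DivergenceError(f"non-finite temperatures at t={t:.3f}s")
        if step % record_every == 0:
            fields.append(
                ThermalField(T.reshape(grid.shape).copy(), grid, steady=False, time=t)
            )
    return fields


def solve_scenario(scenario: Scenario) -> ThermalField:
    """Build the grid for a Scenario and solve its steady state."""
    from .grid import build_scenario_grid

    grid = build_scenario_grid(scenario)
    return solve_steady(
        grid,
        scenario.material_map,
        scenario.ambient,
        actuator_power_mw=scenario.actuator.power_mw,
    )


def probe_temperature(field: ThermalField, position: Iterable[float]) -> float:
    """Trilinear interpolation of the field at a point (mm coordinates)."""
    from scipy.interpolate import RegularGridInterpolator

    pos = np.asarray(tuple(position), dtype=float)
    lo, hi = field.grid.bbox
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError(f"probe position {pos} outside domain box {lo}..{hi}")
    interp = RegularGridInterpolator(
        tuple(field.grid.cell_centers(a) for a in range(3)),
        field.temperature,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    return float(interp(pos)[0])


def sensor_positions(layout: SensorLayout) -> dict[str, tuple[float, float, float]]:
    """Probe coordinates for the six thermistors, in CHANNEL_NAMES order.

    Upstream at -L, downstream at +L on the flow axis; the reference sits at
    lateral distance L perpendicular to the flow axis (off the vessel track).
    Bottom layer on the skin plane z = 0, top layer at z = H.
    """
    L = layout.lateral_offset
    H = layout.interlayer_spacing
    return {
        "t_top_up": (-L, 0.0, H),
        "t_top_dn": (L, 0.0, H),
        "t_top_ref": (0.0, L, H),
        "t_bot_up": (-L, 0.0, 0.0),
        "t_bot_dn": (L, 0.0, 0.0),
        "t_bot_ref": (0.0, L, 0.0),
    }


def sensor_readings(field: ThermalField, layout: SensorLayout) -> np.ndarray:
    """Six probe temperatures in the fixed CHANNEL_NAMES order (deg C)."""
    pos = sensor_positions(layout)
    return np.array([probe_temperature(field, pos[name]) for name in CHANNEL_NAMES])


def normalized_reading(T: float | np.ndarray, T_min: float, T_max: float):
    """Minimum-maximum normalized reading S_N = (T - T_min)/(T_max - T_min)."""
    if not T_max > T_min:
        raise ValueError("degenerate range: T_max must exceed T_min")
    return (T - T_min) / (T_max - T_min)


def power_density(P: float, D: float) -> float:
    """Areal power density P / (pi (D/2)^2); mW and mm in, mW/mm^2 out."""
    if D <= 0:
        raise ValueError("actuator diameter must be positive")
    if P < 0:
        raise ValueError("power must be nonnegative")
    return P / (math.pi * (D / 2) ** 2)


def energy_balance_residual(
    field: ThermalField,
    materials: dict[str, MaterialProperties],
    ambient: AmbientConditions,
    actuator_power_mw: float,
) -> float:
    """Steady-state global energy closure by surface integration.

    Sums conduction through the fixed-temperature bottom, convective loss at
    the top, inlet conduction and the net advected enthalpy, and compares the
    total against the injected actuator power.  Returns the fractional
    imbalance |P_in - P_out| / P_in, or the absolute imbalance in mW when
    P_in = 0.
    """
    grid = field.grid
    T = field.temperature
    sp_m = grid.spacing * 1e-3
    area = sp_m**2
    kcell = _cell_property(grid, materials, "thermal_conductivity")
    rc = _cell_property(grid, materials, "volumetric_heat_capacity")
    u = grid.velocity_x * 1e-3
    fluid = grid.fluid_mask()

    loss = 0.0
    if ambient.bottom_surface_temperature is not None:
        loss += float(
            np.sum(2.0 * kcell[:, :, 0] * sp_m
                   * (T[:, :, 0] - ambient.bottom_surface_temperature))
        )
    h = ambient.convective_coefficient
    if h > 0:
        U = area / (1.0 / h + (grid.spacing * 5e-4) / kcell[:, :, -1])
        loss += float(np.sum(U * (T[:, :, -1] - ambient.ambient_temperature)))
    fin = fluid[0] & (u[0] > 0)
    fout = fluid[-1]
    if fin.any():
        loss += float(
            np.sum(2.0 * kcell[0][fin] * sp_m
                   * (T[0][fin] - ambient.inlet_fluid_temperature))
        )
        m_in = rc[0][fin] * np.abs(u[0][fin]) * area
        loss -= float(np.sum(m_in * ambient.inlet_fluid_temperature))
    if fout.any():
        m_out = rc[-1][fout] * np.abs(u[-1][fout]) * area
        loss += float(np.sum(m_out * T[-1][fout]))

    p_in = actuator_power_mw * 1e-3
    if p_in == 0:
        return abs(loss) * 1e3  # mW
    return abs(p_in - loss) / p_in
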