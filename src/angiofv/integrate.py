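"""Explicit, stability-controlled time integration of the coupled system.

Forward Euler with a time step recomputed every step from a combined
diffusion/drift positivity bound.  Under that bound each update writes
the new cell value as a nonnegative combination of old values, so both
fields stay nonnegative for all time without any clipping, and the flux
form of the spatial operators gives exact discrete mass balance: per
step, the v-mass changes by dt·(Robin influx − consumption) and the
u-mass is constant under the default zero-chemotactic-boundary-flux
closure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import SimulationConfig
from .diagnostics import DiagnosticsRecord
from .grid import BoundaryPartition, Grid, build_grid, default_partition
from .model import ModelParams, chemotactic_sensitivity, consumption_rate, initial_fields
from .operators import (
    FieldBC,
    ScalarField,
    chemotaxis_divergence,
    diffusion_divergence,
    neumann_bc,
    robin_ghost_factor,
    taf_bc,
)

__all__ = [
    "SimulationState",
    "Trajectory",
    "BoundarySetup",
    "StabilityError",
    "SimulationDivergedError",
    "stable_timestep",
    "step",
    "run",
]

#: Fraction of the positivity bound actually used per step.
SAFETY = 0.9
#: Regularizer so a zero drift field yields a finite advective bound.
EPS_DRIFT = 1e-12
#: Abort when a field maximum exceeds this (fields start <= 1).
BLOWUP_LIMIT = 1e6


class StabilityError(RuntimeError):
    """A step was requested with dt above the positivity/stability bound."""


class SimulationDivergedError(RuntimeError):
    """Field magnitudes blew up or turned non-finite/negative mid-run."""


@dataclass
class SimulationState:
    """The pair of fields (u, v) at one time point."""

    t: float
    u: ScalarField
    v: ScalarField

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be nonnegative")
        if np.any(self.u.values < 0) or np.any(self.v.values < 0):
            raise ValueError("model fields u, v must be nonnegative")

    @property
    def grid(self) -> Grid:
        return self.u.grid


@dataclass(frozen=True)
class BoundarySetup:
    """Boundary-condition bundle for one run: where the tumor is and
    whether ECs may drift out through its interface."""

    partition: BoundaryPartition
    u_leak: bool = False

    def bc_u(self) -> FieldBC:
        return neumann_bc()

    def bc_v(self, params: ModelParams) -> FieldBC:
        return taf_bc(self.partition, params.mu)


@dataclass
class Trajectory:
    """Diagnostics time series plus snapshot states of one run."""

    diagnostics: list[DiagnosticsRecord]
    snapshots: list[SimulationState]
    grid: Grid
    partition: BoundaryPartition
    config: SimulationConfig | None = None
    n_steps: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.array([rec.t for rec in self.diagnostics])

    def to_frame(self):
        """Diagnostics as a pandas DataFrame (one row per record)."""
        import pandas as pd

        return pd.DataFrame([vars(rec) for rec in self.diagnostics])


def _max_drift_speed(state: SimulationState, params: ModelParams) -> float:
    """Largest chemotactic face velocity |χ(v_face)·∂v/∂n| on the grid,
    including the Robin influx face at the tumor edge."""
    v = state.v.values
    h = state.grid.h
    amax = 0.0
    for lo, hi in ((v[:-1, :], v[1:, :]), (v[:, :-1], v[:, 1:])):
        drift = np.abs(hi - lo) / h * chemotactic_sensitivity(0.5 * (hi + lo), params)
        amax = max(amax, float(drift.max(initial=0.0)))
    if params.mu > 0:
        # Robin face: (v_g - v_b)/h = v_b * 2mu/(2 - h*mu)
        gradient = v * (2.0 * params.mu / (2.0 - h * params.mu))
        amax = max(amax, float(np.max(chemotactic_sensitivity(v, params) * gradient)))
    return amax


def stable_timestep(params: ModelParams, grid: Grid, state: SimulationState) -> float:
    """Largest explicit step that keeps the upwind update positive.

    The forward-Euler update of a cell is a nonnegative combination of
    old values whenever dt times the largest per-cell outflow rate is
    below 1; the two fields give the rates

        u:  4·Du/h² + 4·a_max/h          (diffusion + donor-cell drift)
        v:  4·Dv·(1 + h·μ)/h² + γ·max u  (diffusion + Robin margin + decay)

    and the step is SAFETY (=0.9) over the larger of the two.
    """
    h = grid.h
    amax = _max_drift_speed(state, params)
    rate_u = 4.0 * params.Du / h**2 + 4.0 * (amax + EPS_DRIFT) / h
    rate_v = 4.0 * params.Dv * (1.0 + h * params.mu) / h**2 + params.gamma * float(
        state.u.values.max(initial=0.0)
    )
    return SAFETY / max(rate_u, rate_v)


def step(
    state: SimulationState,
    dt: float,
    params: ModelParams,
    bcs: BoundarySetup,
    check_dt: bool = True,
) -> SimulationState:
    """Advance both fields one forward-Euler step of size dt.

    Rejects dt above the positivity bound (without the safety factor);
    raises if the update produces NaN or negative values, which would
    indicate a scheme bug rather than a recoverable condition.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if check_dt and dt > stable_timestep(params, state.grid, state) / SAFETY * (1 + 1e-9):
        raise StabilityError(
            f"dt={dt:g} exceeds the positivity-preserving bound at t={state.t:g}"
        )
    u, v = state.u, state.v
    bc_u, bc_v = bcs.bc_u(), bcs.bc_v(params)

    du = (
        diffusion_divergence(u, params.Du, bc_u).values
        + chemotaxis_divergence(u, v, params, bc_v, u_leak=bcs.u_leak).values
    )
    dv = diffusion_divergence(v, params.Dv, bc_v).values + consumption_rate(
        u.values, v.values, params
    )

    u_new = u.values + dt * du
    v_new = v.values + dt * dv
    for name, arr in (("u", u_new), ("v", v_new)):
        if not np.all(np.isfinite(arr)):
            raise SimulationDivergedError(f"{name} turned non-finite at t={state.t:g}")
        if np.any(arr < 0):
            raise SimulationDivergedError(
                f"{name} went negative at t={state.t:g}: positivity violated"
            )
    return SimulationState(
        t=state.t + dt,
        u=ScalarField(u_new, state.grid),
        v=ScalarField(v_new, state.grid),
    )


def initial_state(grid: Grid, partition: BoundaryPartition) -> SimulationState:
    """The closed-form initial fields evaluated at cell centers, at t=0."""
    u0, v0 = initial_fields(grid, partition)
    return SimulationState(t=0.0, u=ScalarField(u0, grid), v=ScalarField(v0, grid))


def run(
    config: SimulationConfig, initial: SimulationState | None = None
) -> Trajectory:
    """Integrate from t=0 to t_end, recording diagnostics and snapshots.

    Diagnostics are recorded at t=0, every ``diag_stride`` accepted steps,
    at every snapshot time (the step is clipped to land on them exactly)
    and at the final time.  Fully deterministic: identical configurations
    give bit-identical trajectories.
    """
    grid = build_grid(config.n)
    partition = default_partition(config.tumor_edge)
    bcs = BoundarySetup(partition=partition, u_leak=config.u_leak)
    params = config.params
    # validate the Robin ghost formula is well-posed at this resolution
    robin_ghost_factor(grid.h, params.mu)

    state = initial if initial is not None else initial_state(grid, partition)
    if state.grid.shape != grid.shape:
        raise ValueError("initial state does not match the configured grid")

    t_end = config.time.t_end
    events = sorted(set(config.time.snapshot_times) | {t_end})
    snap_times = set(config.time.snapshot_times)
    stride = config.time.diag_stride

    diagnostics: list[DiagnosticsRecord] = []
    snapshots: list[SimulationState] = []

    def record(s: SimulationState) -> None:
        diagnostics.append(DiagnosticsRecord.measure(s.t, s.u, s.v, partition))

    record(state)
    if 0.0 in snap_times:
        snapshots.append(replace(state))

    n_steps = 0
    for t_ev in events:
        if t_ev <= state.t + 1e-14:
            continue
        while state.t < t_ev - 1e-14:
            dt_max = (
                stable_timestep(params, grid, state)
                if config.time.dt is None
                else config.time.dt
            )
            dt = min(dt_max, t_ev - state.t)
            # dt from the adaptive bound needs no re-check inside step
            state = step(state, dt, params, bcs, check_dt=config.time.dt is not None)
            n_steps += 1
            if abs(state.t - t_ev) < 1e-12:
                state.t = t_ev
            if float(max(state.u.values.max(), state.v.values.max())) > BLOWUP_LIMIT:
                raise SimulationDivergedError(
                    f"field maximum exceeded {BLOWUP_LIMIT:g} at t={state.t:g}"
                )
            at_event = state.t >= t_ev - 1e-14
            if n_steps % stride == 0 or at_event:
                record(state)
        if state.t in snap_times or (t_ev in snap_times and abs(state.t - t_ev) < 1e-12):
            snapshots.append(replace(state))

    return Trajectory(
        diagnostics=diagnostics,
        snapshots=snapshots,
        grid=grid,
        partition=partition,
        config=config,
        n_steps=n_steps,
    )
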