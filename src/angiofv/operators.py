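"""Conservative finite-volume spatial operators with ghost-cell BCs.

Diffusion is the standard 5-point flux divergence; the chemotactic drift
is discretized with first-order donor-cell upwinding on face velocities,
the classical positivity-preserving treatment of Keller–Segel transport.
Boundary conditions enter through one layer of ghost cells:

* ``neumann_zero`` mirrors the boundary cell (zero normal flux),
* ``robin`` enforces ∂v/∂n = μ v at the face with the second-order
  face-centered formula v_ghost = v_b (2 + hμ) / (2 − hμ).

Both operators are written in flux form, so the cell-area-weighted sum of
either divergence telescopes exactly to the net boundary flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import EDGES, BoundaryPartition, Edge, Grid
from .model import ModelParams, chemotactic_sensitivity

__all__ = [
    "ScalarField",
    "EdgeCondition",
    "FieldBC",
    "neumann_bc",
    "taf_bc",
    "robin_ghost",
    "robin_ghost_factor",
    "diffusion_divergence",
    "chemotaxis_divergence",
]


@dataclass
class ScalarField:
    """A scalar field sampled at cell centers, tied to its grid."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite entries")

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.grid)


@dataclass(frozen=True)
class EdgeCondition:
    """Boundary condition on one edge: zero-flux Neumann or Robin(μ)."""

    kind: str  # "neumann_zero" | "robin"
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("neumann_zero", "robin"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.mu < 0:
            raise ValueError("Robin coefficient mu must be nonnegative")


@dataclass(frozen=True)
class FieldBC:
    """Per-edge boundary conditions for one scalar field."""

    top: EdgeCondition
    bottom: EdgeCondition
    left: EdgeCondition
    right: EdgeCondition

    def on(self, edge: Edge) -> EdgeCondition:
        if edge not in EDGES:
            raise ValueError(f"unknown edge {edge!r}")
        return getattr(self, edge)


def neumann_bc() -> FieldBC:
    """Homogeneous Neumann (no-flux) on all four edges — the EC default."""
    ec = EdgeCondition("neumann_zero")
    return FieldBC(top=ec, bottom=ec, left=ec, right=ec)


def taf_bc(partition: BoundaryPartition, mu: float) -> FieldBC:
    """TAF boundary conditions: Robin(μ) on the tumor edge, no-flux elsewhere."""
    conds = {edge: EdgeCondition("neumann_zero") for edge in EDGES}
    conds[partition.tumor_edge] = EdgeCondition("robin", mu=mu)
    return FieldBC(**conds)


def robin_ghost_factor(h: float, mu: float) -> float:
    """Ghost multiplier (2 + hμ)/(2 − hμ) realizing ∂v/∂n = μ v at a face.

    With v_g = factor · v_b the centered normal derivative (v_g − v_b)/h
    equals μ times the face value (v_g + v_b)/2, keeping the diffusion
    stencil second-order up to the boundary.  Requires hμ < 2.
    """
    if h * mu >= 2.0:
        raise ValueError(
            f"Robin ghost formula ill-posed for h*mu = {h * mu:g} >= 2; refine the grid"
        )
    return (2.0 + h * mu) / (2.0 - h * mu)


def robin_ghost(v_b, h: float, mu: float):
    """Ghost-cell value outside a Robin face, given the boundary cell value."""
    return v_b * robin_ghost_factor(h, mu)


def _pad_with_ghosts(values: np.ndarray, grid: Grid, bc: FieldBC) -> np.ndarray:
    """Surround the field with one ghost layer realizing ``bc``.

    Corners are filled by mirroring but are never read by the 5-point or
    face-flux stencils.
    """
    h = grid.h
    p = np.empty((grid.nx + 2, grid.ny + 2), dtype=float)
    p[1:-1, 1:-1] = values

    def factor(edge: Edge) -> float:
        cond = bc.on(edge)
        return 1.0 if cond.kind == "neumann_zero" else robin_ghost_factor(h, cond.mu)

    p[0, 1:-1] = values[0, :] * factor("left")
    p[-1, 1:-1] = values[-1, :] * factor("right")
    p[1:-1, 0] = values[:, 0] * factor("bottom")
    p[1:-1, -1] = values[:, -1] * factor("top")
    p[0, 0], p[0, -1] = p[1, 0], p[1, -1]
    p[-1, 0], p[-1, -1] = p[-2, 0], p[-2, -1]
    return p


def diffusion_divergence(f: ScalarField, D: float, bc: FieldBC) -> ScalarField:
    """Conservative 5-point divergence of the diffusive flux D∇f.

    Returns D·Σ_faces (f_nb − f_c)/h² per cell, with ghost neighbors from
    ``bc``.  Exactly zero for a constant field under all-Neumann.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    g = f.grid
    p = _pad_with_ghosts(f.values, g, bc)
    c = f.values
    lap = (p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * c) / g.h**2
    return ScalarField(D * lap, g)


def chemotaxis_divergence(
    u: ScalarField,
    v: ScalarField,
    params: ModelParams,
    v_bc: FieldBC,
    u_leak: bool = False,
) -> ScalarField:
    """Upwind divergence of the chemotactic flux, −∇·(χ(v) u ∇v).

    Face drift a = χ(v_face)·(v_R − v_L)/h with v_face the arithmetic
    mean of the adjacent cells; the advected u is taken from the donor
    cell (the side the drift leaves).  Zero drift carries zero flux.

    By default the chemotactic flux through every boundary face is closed
    to zero, so EC mass is conserved even at the tumor edge where
    ∂v/∂n = μv ≠ 0.  With ``u_leak=True`` the tumor-edge face instead
    uses the Robin ghost value of v, letting ECs drift out through the
    tumor interface (the literal reading of ∂u/∂n = 0 on the diffusive
    flux only).
    """
    g = u.grid
    if v.grid is not g and v.grid != g:
        raise ValueError("u and v must share a grid")
    h = g.h

    up = _pad_with_ghosts(u.values, g, neumann_bc())
    vp = _pad_with_ghosts(v.values, g, v_bc)

    # x faces: (nx+1, ny); face k sits between padded cells k and k+1
    vL, vR = vp[:-1, 1:-1], vp[1:, 1:-1]
    a_x = chemotactic_sensitivity(0.5 * (vL + vR), params) * (vR - vL) / h
    Fx = np.where(a_x > 0.0, up[:-1, 1:-1], up[1:, 1:-1]) * a_x

    # y faces: (nx, ny+1)
    vB, vT = vp[1:-1, :-1], vp[1:-1, 1:]
    a_y = chemotactic_sensitivity(0.5 * (vB + vT), params) * (vT - vB) / h
    Fy = np.where(a_y > 0.0, up[1:-1, :-1], up[1:-1, 1:]) * a_y

    if not u_leak:
        Fx[0, :] = Fx[-1, :] = 0.0
        Fy[:, 0] = Fy[:, -1] = 0.0

    div = (Fx[1:, :] - Fx[:-1, :]) / h + (Fy[:, 1:] - Fy[:, :-1]) / h
    return ScalarField(-div, g)
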