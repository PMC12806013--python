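"""Independent brute-force reference implementations for the stencil tests.

Everything here is written with explicit Python loops over cells and
faces, sharing no code with the package's vectorized operators, so it
can serve as an oracle for them on small grids.
"""

from __future__ import annotations

import numpy as np


def ref_ghost(value: float, h: float, kind: str, mu: float) -> float:
    if kind == "neumann_zero":
        return value
    if kind == "robin":
        return value * (2.0 + h * mu) / (2.0 - h * mu)
    raise ValueError(kind)


def _edge_of_neighbor(i: int, j: int, nx: int, ny: int) -> str | None:
    """Which edge a (possibly out-of-range) neighbor index falls outside."""
    if i < 0:
        return "left"
    if i >= nx:
        return "right"
    if j < 0:
        return "bottom"
    if j >= ny:
        return "top"
    return None


def ref_diffusion(values: np.ndarray, h: float, D: float, bc: dict) -> np.ndarray:
    """Flux-by-flux 5-point diffusion divergence; ``bc`` maps edge name to
    ("neumann_zero"|"robin", mu)."""
    nx, ny = values.shape
    out = np.zeros_like(values)
    for i in range(nx):
        for j in range(ny):
            acc = 0.0
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                edge = _edge_of_neighbor(ii, jj, nx, ny)
                if edge is None:
                    nb = values[ii, jj]
                else:
                    kind, mu = bc[edge]
                    nb = ref_ghost(values[i, j], h, kind, mu)
                acc += (nb - values[i, j]) / h**2
            out[i, j] = D * acc
    return out


def ref_chemotaxis(
    u: np.ndarray,
    v: np.ndarray,
    h: float,
    chi: float,
    alpha: float,
    v_bc: dict,
    u_leak: bool,
) -> np.ndarray:
    """Face-by-face donor-cell chemotactic divergence, −∇·(χ(v) u ∇v)."""
    nx, ny = u.shape
    out = np.zeros_like(u)

    def cell_or_ghost(arr, i, j, bc_map):
        edge = _edge_of_neighbor(i, j, nx, ny)
        if edge is None:
            return arr[i, j], False
        # mirror back to the adjacent interior cell for the ghost formula
        ii = min(max(i, 0), nx - 1)
        jj = min(max(j, 0), ny - 1)
        kind, mu = bc_map[edge]
        return ref_ghost(arr[ii, jj], h, kind, mu), True

    u_bc = {e: ("neumann_zero", 0.0) for e in ("top", "bottom", "left", "right")}

    for i in range(nx):
        for j in range(ny):
            div = 0.0
            # the four faces of cell (i,j); normal sign +1 toward the neighbor
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                v_nb, is_boundary = cell_or_ghost(v, ii, jj, v_bc)
                if is_boundary and not u_leak:
                    continue  # closed boundary face: no chemotactic flux
                u_nb, _ = cell_or_ghost(u, ii, jj, u_bc)
                grad_out = (v_nb - v[i, j]) / h  # outward-directed component
                s = chi / (1.0 + alpha * 0.5 * (v_nb + v[i, j]))
                a = s * grad_out
                donor = u[i, j] if a > 0 else u_nb
                div += a * donor / h  # outward flux leaves the cell
            out[i, j] = -div
    return out


def ref_step(
    u: np.ndarray,
    v: np.ndarray,
    h: float,
    dt: float,
    Du: float,
    Dv: float,
    chi: float,
    alpha: float,
    gamma: float,
    mu: float,
    tumor_edge: str,
    u_leak: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward-Euler update assembled entirely from the loops above."""
    edges = ("top", "bottom", "left", "right")
    u_bc = {e: ("neumann_zero", 0.0) for e in edges}
    v_bc = {e: ("neumann_zero", 0.0) for e in edges}
    v_bc[tumor_edge] = ("robin", mu)
    du = ref_diffusion(u, h, Du, u_bc) + ref_chemotaxis(u, v, h, chi, alpha, v_bc, u_leak)
    dv = ref_diffusion(v, h, Dv, v_bc) - gamma * u * v
    return u + dt * du, v + dt * dv
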