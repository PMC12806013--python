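"""Model parameters, chemotactic sensitivity, TAF consumption, initial data.

The model couples the endothelial-cell (EC) density u and the tumor
angiogenic factor (TAF) concentration v on the unit square:

    ∂u/∂t = ∇·(Du ∇u − χ(v) u ∇v),        χ(v) = χ / (1 + α v)
    ∂v/∂t = Dv Δv − γ u v

with no-flux walls for u everywhere, no-flux walls for v on the lateral
and vessel edges, and a Robin influx ∂v/∂n = μ v on the tumor edge (the
leaky tumor interface releasing TAF into the tissue).

χ is the maximum chemotactic response, α the severity of receptor
desensitization at high TAF levels, γ the EC–TAF consumption coefficient
and μ the strength of the tumor's TAF release.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, pi, sin
import numpy as np

from .grid import BoundaryPartition, Grid

__all__ = [
    "ModelParams",
    "TimeConfig",
    "BENCHMARK_PARAMS",
    "chemotactic_sensitivity",
    "consumption_rate",
    "initial_endothelial",
    "initial_taf",
    "initial_fields",
]


@dataclass(frozen=True)
class ModelParams:
    """The six scalars of the coupled system.

    Defaults are the benchmark set used throughout the parameter study:
    Du=0.0035, Dv=0.01, chi=1, alpha=0.6, gamma=0.1, mu=0.5.  Lengths are
    scaled so the domain is the unit square (physically ~1 mm of tissue);
    concentrations are dimensionless.
    """

    Du: float = 0.0035
    Dv: float = 0.01
    chi: float = 1.0
    alpha: float = 0.6
    gamma: float = 0.1
    mu: float = 0.5

    def __post_init__(self) -> None:
        for name in ("Du", "Dv", "chi", "alpha", "gamma", "mu"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise ValueError(f"parameter {name} must be finite, got {val!r}")
        if self.Du <= 0 or self.Dv <= 0:
            raise ValueError("diffusion coefficients Du, Dv must be positive")
        for name in ("chi", "alpha", "gamma", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be nonnegative")

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


#: The benchmark parameter set all experiments perturb one value of.
BENCHMARK_PARAMS = ModelParams()


@dataclass(frozen=True)
class TimeConfig:
    """Time window, step control and snapshot request.

    ``dt=None`` means the step is chosen adaptively from the stability
    bound each step (the default); an explicit dt must lie in (0, t_end]
    and is still subject to the stability check.
    """

    t_end: float = 2.0
    dt: float | None = None
    snapshot_times: tuple[float, ...] = (0.0, 1.0, 2.0)
    diag_stride: int = 100

    def __post_init__(self) -> None:
        if not (self.t_end >= 0 and np.isfinite(self.t_end)):
            raise ValueError(f"t_end must be a nonnegative finite real, got {self.t_end}")
        if self.dt is not None and not (0 < self.dt <= self.t_end):
            raise ValueError(f"explicit dt must lie in (0, t_end], got {self.dt}")
        snaps = tuple(float(t) for t in self.snapshot_times)
        if any(t < 0 or t > self.t_end for t in snaps):
            raise ValueError("snapshot times must lie within [0, t_end]")
        if list(snaps) != sorted(snaps):
            raise ValueError("snapshot times must be sorted ascending")
        if self.diag_stride < 1:
            raise ValueError("diag_stride must be >= 1")
        object.__setattr__(self, "snapshot_times", snaps)


def chemotactic_sensitivity(v, params: ModelParams):
    """Receptor-saturating chemotactic response χ(v) = χ / (1 + α v).

    Decreasing in v for α > 0 (desensitization at high TAF), equal to χ
    at v = 0.  Accepts scalars or arrays; v must be nonnegative.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("TAF concentration v must be nonnegative")
    out = params.chi / (1.0 + params.alpha * v)
    return float(out) if out.ndim == 0 else out


def consumption_rate(u, v, params: ModelParams):
    """TAF sink −γ·u·v: ECs bind and consume TAF where both are present."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("fields u, v must be nonnegative")
    out = -params.gamma * u * v
    return float(out) if out.ndim == 0 else out


def initial_endothelial(x: float, y: float) -> float:
    """Initial EC density: three sprout tips on the parent vessel at y=0.

    u(x, y, 0) = max(0, exp(−y²/0.001) · sin(6πx)) — three nonnegative
    sine peaks hugging the vessel edge in a strip of width ~0.03.
    """
    return max(0.0, exp(-(y * y) / 0.001) * sin(6.0 * pi * x))


def initial_taf(x: float, y: float) -> float:
    """Initial TAF profile: v(x, y, 0) = exp(−(1−y)/0.45).

    Independent of x, equal to 1 on the tumor edge y=1 and decaying
    toward the parent vessel.
    """
    return exp(-(1.0 - y) / 0.45)


def _vessel_frame(grid: Grid, partition: BoundaryPartition) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (w, s): s = distance from the vessel edge toward the
    tumor edge, w = lateral coordinate.  For the default layout (tumor at
    top) this is simply (x, y)."""
    X, Y = grid.meshgrid()
    tumor = partition.tumor_edge
    if tumor == "top":
        return X, Y
    if tumor == "bottom":
        return X, 1.0 - Y
    if tumor == "right":
        return Y, X
    # tumor == "left"
    return Y, 1.0 - X


def initial_fields(grid: Grid, partition: BoundaryPartition) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate both initial conditions at cell centers.

    The closed-form profiles are written for the default layout (tumor at
    y=1); for other tumor-edge assignments they are rotated with the
    geometry.  Tiny negative values from roundoff are clipped to zero
    here, at initialization only.
    """
    W, S = _vessel_frame(grid, partition)
    u0 = np.maximum(0.0, np.exp(-(S * S) / 0.001) * np.sin(6.0 * np.pi * W))
    v0 = np.exp(-(1.0 - S) / 0.45)
    return u0, v0
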