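"""Cell-centered grid on the unit square and the boundary partition.

The extracellular matrix is modeled as the unit square Ω = (0,1)².  The
tumor sits along one edge, the parent vessel along the opposite edge, and
the two remaining edges are lateral walls.  The solver is finite-volume:
unknowns live at cell centers, fluxes on cell faces, and boundary
conditions are imposed through ghost cells one layer outside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Edge",
    "Grid",
    "BoundaryPartition",
    "build_grid",
    "default_partition",
    "opposite_edge",
]

#: The four edges of the unit square, named by their geometric position.
EDGES = ("top", "bottom", "left", "right")

Edge = str  # one of EDGES

_OPPOSITE = {"top": "bottom", "bottom": "top", "left": "right", "right": "left"}


def opposite_edge(edge: Edge) -> Edge:
    """Return the geometrically opposite edge of the unit square."""
    try:
        return _OPPOSITE[edge]
    except KeyError:
        raise ValueError(f"unknown edge {edge!r}; expected one of {EDGES}") from None


@dataclass(frozen=True)
class Grid:
    """Uniform cell-centered n×n lattice on the unit square.

    Attributes
    ----------
    nx, ny : int
        Number of cells in x and y.  Cells are square, so ``nx == ny``
        on the unit square.
    h : float
        Cell width, ``1 / nx``.
    """

    nx: int
    ny: int
    h: float

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError(
                f"grid resolution {self.nx}x{self.ny} too coarse; need at least 4x4"
            )
        if not (np.isclose(self.h * self.nx, 1.0) and np.isclose(self.h * self.ny, 1.0)):
            raise ValueError("cells must tile the unit square: h*nx = h*ny = 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    @property
    def x(self) -> np.ndarray:
        """Cell-center x coordinates, shape (nx,)."""
        return (np.arange(self.nx) + 0.5) * self.h

    @property
    def y(self) -> np.ndarray:
        """Cell-center y coordinates, shape (ny,)."""
        return (np.arange(self.ny) + 0.5) * self.h

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinate arrays X, Y of shape (nx, ny)."""
        return np.meshgrid(self.x, self.y, indexing="ij")

    def edge_slice(self, edge: Edge) -> tuple[slice | int, slice | int]:
        """Index of the single row/column of cells adjacent to ``edge``.

        Fields are indexed ``values[i, j]`` with i the x index and j the
        y index, so ``values[grid.edge_slice("top")]`` is the cell row
        touching y = 1.
        """
        if edge == "left":
            return (0, slice(None))
        if edge == "right":
            return (self.nx - 1, slice(None))
        if edge == "bottom":
            return (slice(None), 0)
        if edge == "top":
            return (slice(None), self.ny - 1)
        raise ValueError(f"unknown edge {edge!r}; expected one of {EDGES}")


@dataclass(frozen=True)
class BoundaryPartition:
    """Assignment of the square's four edges to tumor, vessel and walls.

    ``tumor_edge`` carries the Robin TAF influx, ``vessel_edge`` is the
    parent vessel the endothelial sprouts emanate from, and the two
    ``lateral_edges`` are plain no-flux walls.  Tumor and vessel are
    always geometrically opposite.
    """

    tumor_edge: Edge

    @property
    def vessel_edge(self) -> Edge:
        return opposite_edge(self.tumor_edge)

    @property
    def lateral_edges(self) -> tuple[Edge, Edge]:
        used = {self.tumor_edge, self.vessel_edge}
        return tuple(e for e in EDGES if e not in used)  # type: ignore[return-value]

    def __post_init__(self) -> None:
        if self.tumor_edge not in EDGES:
            raise ValueError(
                f"unknown edge {self.tumor_edge!r}; expected one of {EDGES}"
            )


def build_grid(n: int) -> Grid:
    """Build an n×n cell-centered grid on the unit square (h = 1/n)."""
    n = int(n)
    if n < 4:
        raise ValueError(f"grid resolution n={n} too coarse; need n >= 4")
    return Grid(nx=n, ny=n, h=1.0 / n)


def default_partition(tumor_edge: Edge = "top") -> BoundaryPartition:
    """Default boundary layout: tumor at y=1, parent vessel at y=0.

    The initial TAF profile is maximal at y=1 and the three endothelial
    sprout tips sit on y=0, so by default the tumor edge is the top of
    the square and the vessel edge the bottom.  The assignment is
    configurable; the vessel edge is always opposite the tumor edge.
    """
    return BoundaryPartition(tumor_edge=tumor_edge)
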