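"""Query grids and density surfaces.

The server specifies a rectangular area and an evenly spaced grid of query
coordinates on it; users respond with one real value per grid node.  A
:class:`GridSpec` fixes the geometry (endpoint-inclusive linspace per axis)
and a :class:`Surface` is a real-valued array aligned to it.

Index convention: ``values[p, q]`` corresponds to the node ``(x_p, y_q)``;
the linear index of node ``(p, q)`` is ``p * Q + q``, matching
``values.ravel()``.  In 1D the y axis is absent and surfaces are vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GridSpec", "Surface"]


@dataclass(frozen=True)
class GridSpec:
    """An endpoint-inclusive P (x Q) evaluation grid over a rectangle.

    Parameters
    ----------
    x_range : (float, float)
        Extent along x, ``min < max``.
    P : int
        Number of nodes along x, at least 2.
    y_range : (float, float), optional
        Extent along y; omit for a 1D grid.
    Q : int, optional
        Number of nodes along y; required iff ``y_range`` is given.
    """

    x_range: tuple
    P: int
    y_range: Optional[tuple] = None
    Q: Optional[int] = None

    def __post_init__(self):
        if (self.y_range is None) != (self.Q is None):
            raise ValueError("y_range and Q must be given together")
        if self.P < 2:
            raise ValueError("P must be >= 2")
        lo, hi = self.x_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("x_range must be finite with min < max")
        if self.y_range is not None:
            if self.Q < 2:
                raise ValueError("Q must be >= 2")
            lo, hi = self.y_range
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("y_range must be finite with min < max")

    @property
    def dim(self) -> int:
        return 1 if self.y_range is None else 2

    @property
    def shape(self) -> tuple:
        return (self.P,) if self.dim == 1 else (self.P, self.Q)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(self.x_range[0], self.x_range[1], self.P)

    @property
    def ys(self) -> np.ndarray:
        if self.dim == 1:
            raise ValueError("1D grid has no y axis")
        return np.linspace(self.y_range[0], self.y_range[1], self.Q)

    @property
    def spacing(self) -> tuple:
        """Node spacing per axis."""
        dx = (self.x_range[1] - self.x_range[0]) / (self.P - 1)
        if self.dim == 1:
            return (dx,)
        dy = (self.y_range[1] - self.y_range[0]) / (self.Q - 1)
        return (dx, dy)

    @property
    def cell_area(self) -> float:
        return float(np.prod(self.spacing))

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape ``(n_nodes, dim)``, linear-index order."""
        if self.dim == 1:
            return self.xs[:, None]
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel()], axis=1)

    def coord(self, linear_index: int) -> np.ndarray:
        """Coordinate of the node with the given linear index."""
        if self.dim == 1:
            return np.array([self.xs[linear_index]])
        p, q = divmod(int(linear_index), self.Q)
        return np.array([self.xs[p], self.ys[q]])

    def bounds(self) -> np.ndarray:
        """Axis-aligned bounds, shape ``(dim, 2)``."""
        if self.dim == 1:
            return np.array([self.x_range], dtype=float)
        return np.array([self.x_range, self.y_range], dtype=float)

    def to_dict(self) -> dict:
        d = {"x_range": [float(v) for v in self.x_range], "P": int(self.P)}
        if self.dim == 2:
            d["y_range"] = [float(v) for v in self.y_range]
            d["Q"] = int(self.Q)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            x_range=tuple(d["x_range"]),
            P=int(d["P"]),
            y_range=tuple(d["y_range"]) if d.get("y_range") is not None else None,
            Q=int(d["Q"]) if d.get("Q") is not None else None,
        )


@dataclass
class Surface:
    """Real-valued evaluations aligned to a :class:`GridSpec`.

    ``meta`` records provenance (method tag, bandwidth h, feature count B,
    user count N, seed) and travels with the surface through serialization.
    """

    values: np.ndarray
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"surface shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surface values must be finite")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()
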