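"""Ground-truth Gaussian mixtures for synthetic experiments.

Three built-in study populations:

* ``grid9`` — 9 equal-weight isotropic Gaussians on the lattice
  ``{-1, 0, 1}^2`` with diagonal covariance 0.25 (a smooth, near-uniform
  surface);
* ``octagon8`` — 8 equal-weight anisotropic Gaussians at radius 3, angles
  ``pi i / 4`` for i = 1..8, each a rotated ellipse
  ``R(pi i/4) diag(1, 0.16^2) R(pi i/4)^T`` (a heterogeneous ring);
* ``tri1d`` — 1D mixture N(-10, 2^2), N(0, 2^2), N(5, 2^2) with weights
  1:3:1.

Sampling and the exact mixture density share one dimension-generic code
path; default evaluation grids match the ones the estimators are assessed
on ([-3, 3]^2 at 50x50, [-5, 5]^2 at 100x100, [-15, 15] at 1000 points).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GridSpec, Surface

__all__ = [
    "MixtureSpec",
    "builtin_mixture",
    "default_grid",
    "sample_mixture",
    "mixture_density",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A Gaussian mixture: weights, component means, component covariances.

    ``means`` has shape ``(k, dim)``; ``covariances`` has shape
    ``(k, dim, dim)`` with symmetric positive-definite entries (1D
    variances are stored as 1x1 matrices).
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        m = np.atleast_2d(np.asarray(self.means, dtype=float))
        c = np.asarray(self.covariances, dtype=float)
        if c.ndim == 1:  # per-component variances, 1D
            c = c[:, None, None]
        if not (w.shape[0] == m.shape[0] == c.shape[0]):
            raise ValueError("weights/means/covariances counts differ")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        for ci in c:
            if not np.allclose(ci, ci.T):
                raise ValueError("covariances must be symmetric")
            if np.any(np.linalg.eigvalsh(ci) <= 0):
                raise ValueError("covariances must be positive definite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covariances=np.asarray(d["covariances"], dtype=float),
        )


def _octagon_cov(i: int) -> np.ndarray:
    angle = np.pi * i / 4.0
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([1.0, 0.16**2]) @ rot.T


def builtin_mixture(name: str) -> MixtureSpec:
    """One of the built-in study mixtures: ``grid9``, ``octagon8``, ``tri1d``."""
    if name == "grid9":
        means = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)
        covs = np.tile(np.diag([0.25, 0.25]), (9, 1, 1))
        weights = np.full(9, 1.0 / 9.0)
    elif name == "octagon8":
        idx = np.arange(1, 9)
        means = 3.0 * np.stack([np.cos(np.pi * idx / 4), np.sin(np.pi * idx / 4)], axis=1)
        covs = np.stack([_octagon_cov(i) for i in idx])
        weights = np.full(8, 1.0 / 8.0)
    elif name == "tri1d":
        means = np.array([[-10.0], [0.0], [5.0]])
        covs = np.full((3, 1, 1), 4.0)
        weights = np.array([0.2, 0.6, 0.2])
    else:
        raise ValueError(f"unknown mixture {name!r}")
    return MixtureSpec(weights=weights, means=means, covariances=covs)


def default_grid(name: str) -> GridSpec:
    """Default evaluation grid for a built-in mixture."""
    if name == "grid9":
        return GridSpec(x_range=(-3.0, 3.0), P=50, y_range=(-3.0, 3.0), Q=50)
    if name == "octagon8":
        return GridSpec(x_range=(-5.0, 5.0), P=100, y_range=(-5.0, 5.0), Q=100)
    if name == "tri1d":
        return GridSpec(x_range=(-15.0, 15.0), P=1000)
    raise ValueError(f"unknown mixture {name!r}")


def sample_mixture(spec: MixtureSpec, N: int, rng, return_components: bool = False):
    """Draw ``N`` locations: component by weight, then a Gaussian draw.

    Returns an ``(N, dim)`` array (with the component labels as a second
    value when ``return_components``); fully determined by the generator
    state.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    comps = rng.choice(spec.k, size=N, p=spec.weights)
    z = rng.standard_normal((N, spec.dim))
    chols = np.linalg.cholesky(spec.covariances)  # (k, dim, dim)
    pts = spec.means[comps] + np.einsum("nij,nj->ni", chols[comps], z)
    return (pts, comps) if return_components else pts


def mixture_density(spec: MixtureSpec, grid: GridSpec) -> Surface:
    """Exact (normalized) mixture pdf at every grid node."""
    if spec.dim != grid.dim:
        raise ValueError("mixture and grid dimensions differ")
    nodes = grid.nodes()
    dens = np.zeros(grid.n_nodes)
    for w, mu, cov in zip(spec.weights, spec.means, spec.covariances):
        dens += w * stats.multivariate_normal.pdf(nodes, mean=mu, cov=cov)
    return Surface(dens.reshape(grid.shape), grid, meta={"method": "truth"})
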