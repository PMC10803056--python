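"""The malicious server: localization attack and privacy score.

A server trying to localize a user from a response surface can do no better
than predicting locations at the surface's maxima (the true location always
attains the maximal feature value).  The attack therefore enumerates grid
local maxima, discards weak ones (below ``e_max / epsilon`` of the global
maximum), and scores the expected localization error as the weight-averaged
distance from the kept maxima to the true location.  Large scores mean the
surviving maxima are spread across the map — the user is delocalized.

For a single feature with frequency ``w`` the set of locations a user cannot
be distinguished from is a family of parallel lines (bands) orthogonal to
``w`` with spacing ``2 pi / ||w||``; :func:`equivalence_class_points`
materializes that family clipped to a bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy import ndimage

from .grid import GridSpec, Surface

__all__ = [
    "AttackReport",
    "find_local_maxima",
    "privacy_score_user",
    "privacy_score_system",
    "zero_feature_score",
    "EquivalenceClass",
    "equivalence_class_points",
    "kept_maxima",
    "bandwidth_overlap_period",
]

DEFAULT_EPSILON_FILTER = 1.1


@dataclass
class AttackReport:
    """Outcome of the maxima attack on one user's surface.

    ``indices``/``coords``/``values`` enumerate the surface's local maxima
    (one representative per plateau, lowest linear index).  ``kept`` marks
    maxima surviving the strength filter; ``weights`` are the normalized
    evidence weights over kept maxima (zero elsewhere, summing to 1).
    ``z`` is the user's privacy score: the attacker's expected localization
    error in map units.  ``fallback`` flags the degenerate all-nonpositive
    case where an unweighted mean over all maxima was used instead.
    """

    indices: np.ndarray
    coords: np.ndarray
    values: np.ndarray
    kept: np.ndarray
    weights: np.ndarray
    z: float
    epsilon_filter: float
    fallback: bool = False

    @property
    def K(self) -> int:
        return int(self.indices.size)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "epsilon_filter": self.epsilon_filter,
            "fallback": self.fallback,
            "z": self.z,
            "maxima": [
                {
                    "index": int(i),
                    "coord": [float(c) for c in xy],
                    "value": float(v),
                    "kept": bool(k),
                    "weight": float(w),
                }
                for i, xy, v, k, w in zip(
                    self.indices, self.coords, self.values, self.kept, self.weights
                )
            ],
        }


def find_local_maxima(surface: Surface):
    """Grid local maxima of a surface.

    A cell is a local maximum iff its value is >= all existing neighbors
    (8-neighborhood in 2D, both neighbors in 1D; boundary cells compare only
    the neighbors they have).  Adjacent qualifying cells necessarily share
    one value; each such plateau contributes a single representative, the
    cell with the lowest linear index — so the attack output is
    deterministic.

    Returns ``(indices, coords, values)``: linear indices (sorted), node
    coordinates ``(k, dim)``, and surface values at the maxima.
    """
    vals = surface.values
    size = 3 if vals.ndim == 1 else (3, 3)
    neighborhood_max = ndimage.maximum_filter(vals, size=size, mode="constant", cval=-np.inf)
    mask = vals >= neighborhood_max
    # plateau dedup: adjacent maxima cells are equal-valued by construction
    structure = np.ones((3,) * vals.ndim, dtype=bool)
    labels, n_comp = ndimage.label(mask, structure=structure)
    flat_labels = labels.ravel()
    firsts = np.full(n_comp + 1, flat_labels.size, dtype=int)
    np.minimum.at(firsts, flat_labels, np.arange(flat_labels.size))
    indices = np.sort(firsts[1:])
    nodes = surface.grid.nodes()
    return indices, nodes[indices], vals.ravel()[indices]


def privacy_score_user(
    surface: Surface,
    d_true,
    epsilon_filter: float = DEFAULT_EPSILON_FILTER,
    double_normalize: bool = False,
) -> AttackReport:
    """Attack one user's surface and score the expected localization error.

    Maxima with value below ``e_max / epsilon_filter`` (``e_max`` the
    largest local-maximum value) are discarded; the rest get evidence
    weights proportional to their values, and the score is the weighted
    mean distance from those maxima to ``d_true``.  ``double_normalize``
    additionally divides by the number of kept maxima (the literal
    double-normalized form; the weighted mean is the default as it matches
    the score's "expected error in distance units" reading).

    If no maximum has positive value the weights are undefined; the score
    falls back to the unweighted mean distance over all maxima and the
    report is flagged.
    """
    if epsilon_filter < 1:
        raise ValueError("epsilon_filter must be >= 1")
    d_true = np.asarray(d_true, dtype=float).reshape(-1)
    indices, coords, values = find_local_maxima(surface)
    dists = np.linalg.norm(coords - d_true, axis=1)
    e_max = values.max()
    if e_max <= 0:
        k = values.size
        return AttackReport(
            indices, coords, values,
            kept=np.ones(k, dtype=bool),
            weights=np.full(k, 1.0 / k),
            z=float(dists.mean()),
            epsilon_filter=epsilon_filter,
            fallback=True,
        )
    kept = values >= e_max / epsilon_filter
    weights = np.zeros_like(values)
    weights[kept] = values[kept] / values[kept].sum()
    z = float(np.sum(weights * dists))
    if double_normalize:
        z /= int(kept.sum())
    return AttackReport(indices, coords, values, kept, weights, z, epsilon_filter)


def privacy_score_system(reports: Sequence) -> float:
    """System privacy score: the arithmetic mean of the per-user scores.

    Accepts :class:`AttackReport` objects or raw per-user scores.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to average")
    zs = [r.z if isinstance(r, AttackReport) else float(r) for r in reports]
    return float(np.mean(zs))


def zero_feature_score(grid: GridSpec, d) -> float:
    """Privacy score of the constant (0-feature) response.

    The attacker learns nothing and can only guess uniformly over the grid;
    the expected error is the mean distance from the user to every node.
    This is the best-case privacy bound.
    """
    d = np.asarray(d, dtype=float).reshape(-1)
    return float(np.mean(np.linalg.norm(grid.nodes() - d, axis=1)))


def kept_maxima(surface: Surface, epsilon_filter: float = DEFAULT_EPSILON_FILTER):
    """Coordinates of local maxima surviving the strength filter.

    Convenience view of the attack: maxima with value below
    ``e_max / epsilon_filter`` (e.g. boundary artifacts and shallow ridges)
    are dropped.  Returns the ``(k, dim)`` coordinates.
    """
    _, coords, values = find_local_maxima(surface)
    e_max = values.max()
    if e_max <= 0:
        return coords
    return coords[values >= e_max / epsilon_filter]


def bandwidth_overlap_period(basis, d=0.3, n: int = 1, cycles: float = 2.6,
                             pts_per_period: int = 26) -> int:
    """Band-overlap period between base and rescaled 1D responses.

    Queries a 1D single-feature user once at the base bandwidth ``h0`` and
    once at the policy bandwidth ``(4 n + 1) h0``, finds the surviving
    bands of both responses on a window wide enough to show ``~2 * cycles``
    rescaled bands, and returns the spacing — in base-band counts — at
    which the rescaled bands coincide with base bands.  Under the
    rescaling policy this is exactly ``4 n + 1`` (every rescaled band sits
    on a base band, one in every ``4 n + 1``).

    Raises if any rescaled band fails to land on a base band or the
    coincidence pattern is not periodic.
    """
    from .protocol import user_surface_rff

    if basis.dim != 1 or basis.B != 1:
        raise ValueError("the worked example uses a single 1D feature")
    w = abs(float(basis.omegas[0, 0]))
    if w < 1e-3:
        raise ValueError("frequency too small to show bands on a finite window")
    factor = 4 * n + 1
    period = 2.0 * np.pi / w
    half = cycles * factor * period
    P = max(200, int(round(2 * cycles * factor * pts_per_period)))
    grid = GridSpec((float(d) - half, float(d) + half), P)
    d_arr = np.array([float(d)])
    base = kept_maxima(user_surface_rff(d_arr, basis, basis.h0, grid))[:, 0]
    resc = kept_maxima(user_surface_rff(d_arr, basis, factor * basis.h0, grid))[:, 0]
    base.sort()
    resc.sort()
    ranks = []
    for c in resc:
        k = int(np.argmin(np.abs(base - c)))
        if abs(base[k] - c) > period / 2.0:
            raise ValueError("a rescaled band does not coincide with any base band")
        ranks.append(k)
    gaps = np.diff(ranks)
    if gaps.size == 0 or not np.all(gaps == gaps[0]):
        raise ValueError("band coincidences are not periodic on this window")
    return int(gaps[0])


# ---------------------------------------------------------------------------
# single-feature equivalence classes

@dataclass
class EquivalenceClass:
    """Locations indistinguishable from ``anchor`` under one frequency.

    In 2D the class is the family of lines
    ``{anchor + alpha * 2 pi w / ||w||^2 + u : w^T u = 0, alpha integer}``
    clipped to a bounding box: parallel bands orthogonal to ``w`` spaced
    ``2 pi / ||w||`` apart.  In 1D it degenerates to a point lattice.
    Every member produces exactly the same single-feature response as the
    anchor at every query point.
    """

    anchor: np.ndarray
    omega: np.ndarray
    spacing: float
    alphas: np.ndarray
    # 2D: per-alpha (point on line, unit direction, (s_min, s_max)); 1D: empty
    lines: List[tuple] = field(default_factory=list)
    # 1D lattice members; 2D: empty
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 1)))

    @property
    def dim(self) -> int:
        return self.anchor.size

    def sample_points(self, n_per_line: int, rng) -> np.ndarray:
        """Random members of the class inside the bounding box."""
        if self.dim == 1:
            return self.points
        pts = []
        for base, u, (s0, s1) in self.lines:
            s = rng.uniform(s0, s1, size=n_per_line)
            pts.append(base[None, :] + s[:, None] * u[None, :])
        return np.concatenate(pts, axis=0)


def equivalence_class_points(omega, x, bbox: GridSpec) -> EquivalenceClass:
    """Materialize the single-feature equivalence class of ``x`` in ``bbox``."""
    omega = np.asarray(omega, dtype=float).reshape(-1)
    x = np.asarray(x, dtype=float).reshape(-1)
    norm = np.linalg.norm(omega)
    if norm == 0:
        raise ValueError("omega must be nonzero")
    if omega.size != x.size or omega.size != bbox.dim:
        raise ValueError("omega/x/bbox dimension mismatch")
    spacing = 2.0 * np.pi / norm
    bounds = bbox.bounds()

    if x.size == 1:
        w = omega[0]
        step = 2.0 * np.pi / w  # signed; lattice is the same either sign
        lo, hi = bounds[0]
        a0 = int(np.ceil((lo - x[0]) / abs(step)))
        a1 = int(np.floor((hi - x[0]) / abs(step)))
        alphas = np.arange(a0, a1 + 1)
        points = (x[0] + alphas * abs(step))[:, None]
        return EquivalenceClass(x, omega, spacing, alphas, points=points)

    w_hat = omega / norm
    u_hat = np.array([-w_hat[1], w_hat[0]])
    step = 2.0 * np.pi * omega / norm**2  # advance by one band along w_hat
    corners = np.array(
        [[bounds[0][i], bounds[1][j]] for i in (0, 1) for j in (0, 1)]
    )
    proj = (corners - x) @ w_hat
    a0 = int(np.ceil(proj.min() / spacing))
    a1 = int(np.floor(proj.max() / spacing))
    alphas = np.arange(a0, a1 + 1)

    lines = []
    for a in alphas:
        base = x + a * step
        # clip base + s*u_hat to the box (slab intersection)
        s_lo, s_hi = -np.inf, np.inf
        for axis in range(2):
            if abs(u_hat[axis]) < 1e-15:
                continue
            t0 = (bounds[axis][0] - base[axis]) / u_hat[axis]
            t1 = (bounds[axis][1] - base[axis]) / u_hat[axis]
            s_lo = max(s_lo, min(t0, t1))
            s_hi = min(s_hi, max(t0, t1))
        if s_lo <= s_hi:
            lines.append((base, u_hat, (float(s_lo), float(s_hi))))
    return EquivalenceClass(x, omega, spacing, alphas, lines=lines)
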