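"""The simulated server/user protocol.

The server publishes a :class:`~fedrff.grid.GridSpec` and a bandwidth; each
user answers with a surface of evaluations at every grid node and the server
averages the responses.  Two response modes exist:

* **exact** — the user returns ``k_h(d, g)`` at each node ``g`` (federated
  KDE; zero privacy, since the response peaks at the user's location);
* **rff** — the user returns ``sum_b cos(w_b^T (g - d))`` using B frozen
  random-feature frequencies; the server divides the pooled sum by ``N B``.

Users enforce a bandwidth/feature policy unilaterally: a query is refused if
its bandwidth exceeds the maximum implied by the area size and the user's
band-count risk tolerance, if it is not of the rescaling form
``(4 n + 1) h0``, or if it requests too many features.  Refusal depends only
on public policy parameters, never on the user's location.

The "federation" is in-process: aggregation functions receive only
:class:`~fedrff.grid.Surface` objects, never locations or bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from .grid import GridSpec, Surface
from .kernels import RFFBasis, gaussian_kernel, rescale_frequencies, user_basis

__all__ = [
    "user_surface_exact",
    "user_surface_rff",
    "aggregate",
    "max_bandwidth",
    "BandwidthPolicy",
    "QueryDecision",
    "validate_query",
    "federated_exact_surface",
    "federated_rff_surface",
    "count_bands_in_square",
    "band_count_probability",
    "band_guarantee_level",
]


# ---------------------------------------------------------------------------
# per-user responses

def user_surface_exact(d, grid: GridSpec, h: float) -> Surface:
    """One user's exact kernel evaluations on the grid (federated KDE)."""
    d = np.asarray(d, dtype=float).reshape(-1)
    if d.shape[0] != grid.dim:
        raise ValueError(f"point dim {d.shape[0]} does not match grid dim {grid.dim}")
    vals = gaussian_kernel(d, grid.nodes(), h).reshape(grid.shape)
    return Surface(vals, grid, meta={"method": "exact", "h": float(h), "B": None, "N": 1})


def user_surface_rff(d, basis: RFFBasis, h: float, grid: GridSpec) -> Surface:
    """One user's random-feature response: entrywise ``sum_b cos(w_b^T (g - d))``.

    Entries are sums over the B features (the server divides the pooled total
    by ``N B``), so they lie in ``[-B, B]`` and equal ``B`` at a grid node
    coinciding with ``d``.  Repeated calls with the same (basis, h, grid)
    are bit-identical — the basis is frozen.
    """
    d = np.asarray(d, dtype=float).reshape(-1)
    if d.shape[0] != grid.dim or basis.dim != grid.dim:
        raise ValueError("point/basis/grid dimension mismatch")
    om = rescale_frequencies(basis, h)  # (B, dim)
    args = (grid.nodes() - d) @ om.T  # (n_nodes, B)
    vals = np.sum(np.cos(args), axis=1).reshape(grid.shape)
    return Surface(
        vals, grid, meta={"method": "rff", "h": float(h), "B": basis.B, "N": 1}
    )


def aggregate(surfaces: List[Surface], mode: str, B: Optional[int] = None) -> Surface:
    """Server-side aggregation of user responses.

    ``mode='exact'``: entrywise mean ``(1/N) sum_i``.
    ``mode='rff'``: ``(1/(N B)) sum_i`` of the raw per-user sums, so the
    result is the random-feature density estimate on the grid.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("cannot aggregate an empty list of surfaces")
    grid = surfaces[0].grid
    for s in surfaces[1:]:
        if s.grid != grid:
            raise ValueError("all surfaces must share one GridSpec")
    total = np.sum([s.values for s in surfaces], axis=0)
    n = len(surfaces)
    if mode == "exact":
        vals = total / n
    elif mode == "rff":
        if B is None:
            B = surfaces[0].meta.get("B")
        if not B or B < 1:
            raise ValueError("rff aggregation requires the common feature count B")
        vals = total / (n * B)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    h = surfaces[0].meta.get("h")
    return Surface(vals, grid, meta={"method": mode, "h": h, "B": B, "N": n})


# ---------------------------------------------------------------------------
# bandwidth policy

def max_bandwidth(gamma: float, j: int, l: float) -> float:
    """Largest bandwidth keeping at least ``j`` feature bands in the area.

    For a single 2D feature with ``w ~ N(0, h^-2 I)``, ``||w||^2 ~ h^-2 *
    chi^2_2`` and the number of bands crossing the inscribed square of side
    ``l`` is at least ``l ||w|| / (2 pi)``.  Requiring at least ``j`` bands
    with probability ``1 - C(gamma)`` (``C`` the chi-squared CDF, 2 df)
    yields ``h <= sqrt(gamma) * l / (2 pi j)``.  Monotone increasing in
    ``l`` and ``gamma``, decreasing in ``j``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if j < 2:
        raise ValueError("j must be at least 2")
    if l <= 0:
        raise ValueError("l must be positive")
    return float(np.sqrt(gamma) * l / (2.0 * np.pi * j))


@dataclass(frozen=True)
class QueryDecision:
    """Outcome of user-side policy validation; refusal is a value, not an error."""

    accepted: bool
    reason: Optional[str] = None

    def __bool__(self) -> bool:
        return self.accepted


@dataclass(frozen=True)
class BandwidthPolicy:
    """User-side query policy: base bandwidth, risk bound, and feature cap.

    Parameters
    ----------
    h0 : float
        The user's base bandwidth; frequencies are drawn once at ``h0``.
    gamma : float
        Band-count risk parameter; the guarantee holds with probability
        ``1 - C(gamma)`` where ``C`` is the chi-squared CDF with 2 df.
    j : int
        Minimum number of bands required across the area (at least 2).
    l : float
        Side length of the largest square inscribed in the target area.
    B_max : int
        Maximum number of features the user will evaluate.
    """

    h0: float
    gamma: float
    j: int
    l: float
    B_max: int

    def __post_init__(self):
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if self.j < 2:
            raise ValueError("j must be at least 2")
        if self.gamma <= 0 or self.l <= 0 or self.B_max < 0:
            raise ValueError("invalid policy parameters")

    @property
    def h_max(self) -> float:
        return max_bandwidth(self.gamma, self.j, self.l)

    def in_rescaling_set(self, h: float, rtol: float = 1e-9) -> bool:
        """Is ``h`` of the form ``(4 n + 1) h0`` for integer ``n >= 0``?

        Relative tolerance absorbs decimal round-trips of ``h`` through
        config files.  ``n = 0`` (the base bandwidth itself) is allowed.
        """
        if h <= 0:
            return False
        n = round((h / self.h0 - 1.0) / 4.0)
        if n < 0:
            return False
        return abs(h - (4 * n + 1) * self.h0) <= rtol * abs(h)

    def to_dict(self) -> dict:
        return {
            "h0": self.h0,
            "gamma": self.gamma,
            "j": self.j,
            "l": self.l,
            "B_max": self.B_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandwidthPolicy":
        return cls(
            h0=float(d["h0"]),
            gamma=float(d["gamma"]),
            j=int(d["j"]),
            l=float(d["l"]),
            B_max=int(d["B_max"]),
        )


def validate_query(policy: BandwidthPolicy, h: float, B: int) -> QueryDecision:
    """Accept or refuse a server query ``(h, B)`` under the user's policy.

    The decision depends only on public policy parameters — refusing a query
    reveals nothing about the user's location.
    """
    if h <= 0 or h > policy.h_max:
        return QueryDecision(False, "bandwidth_exceeds_maximum")
    if not policy.in_rescaling_set(h):
        return QueryDecision(False, "bandwidth_not_in_policy_set")
    if B > policy.B_max:
        return QueryDecision(False, "too_many_features")
    return QueryDecision(True, None)


# ---------------------------------------------------------------------------
# whole-population drivers (streaming aggregation; identical results to the
# per-user surface path, without materializing N Surface objects)

def federated_exact_surface(points, grid: GridSpec, h: float, chunk: int = 2048) -> Surface:
    """Pooled federated-KDE surface: mean of all users' exact responses."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != grid.dim:
        raise ValueError("points do not match grid dimension")
    nodes = grid.nodes()
    total = np.zeros(grid.n_nodes)
    for start in range(0, points.shape[0], chunk):
        block = points[start : start + chunk]  # (c, dim)
        sq = np.sum((block[:, None, :] - nodes[None, :, :]) ** 2, axis=-1)
        total += np.exp(-sq / (2.0 * h * h)).sum(axis=0)
    vals = (total / points.shape[0]).reshape(grid.shape)
    return Surface(
        vals,
        grid,
        meta={"method": "exact", "h": float(h), "B": None, "N": int(points.shape[0])},
    )


def federated_rff_surface(
    points,
    grid: GridSpec,
    h: float,
    B: int,
    master_seed: int,
    h0: Optional[float] = None,
    chunk: int = 8192,
) -> Surface:
    """Aggregated random-feature density estimate for a whole population.

    Each user ``i`` draws B frequencies at base bandwidth ``h0`` (default:
    ``h``) from the substream keyed by ``i`` under ``master_seed`` — exactly
    the bases :func:`~fedrff.kernels.user_basis` produces — rescales them to
    ``h``, and responds; the server returns the pooled average
    ``(1/(N B)) sum_{i,b} cos(w_ib^T (g - d_i))``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    N, dim = points.shape
    if dim != grid.dim:
        raise ValueError("points do not match grid dimension")
    if B < 1:
        raise ValueError("B must be >= 1")
    if h0 is None:
        h0 = h
    scale = h0 / h
    nodes = grid.nodes()

    # draw every user's frozen basis from its keyed substream
    omegas = np.empty((N, B, dim))
    for i in range(N):
        omegas[i] = user_basis(master_seed, i, B, h0, dim=dim).omegas
    om_flat = (scale * omegas).reshape(N * B, dim)
    phases = np.einsum("ibd,id->ib", scale * omegas, points).reshape(N * B)

    total = np.zeros(grid.n_nodes)
    for start in range(0, N * B, chunk):
        om = om_flat[start : start + chunk]
        ph = phases[start : start + chunk]
        total += np.cos(om @ nodes.T - ph[:, None]).sum(axis=0)
    vals = (total / (N * B)).reshape(grid.shape)
    return Surface(
        vals,
        grid,
        meta={
            "method": "rff",
            "h": float(h),
            "h0": float(h0),
            "B": int(B),
            "N": int(N),
            "seed": int(master_seed),
        },
    )


# ---------------------------------------------------------------------------
# band-count oracle for the maximum-bandwidth rule

def count_bands_in_square(omega, l: float, d=(0.0, 0.0)) -> int:
    """Number of feature bands of ``cos(w^T (x - d))`` crossing ``[0, l]^2``.

    Bands are the maxima lines ``w^T (x - d) = 2 pi t``; the count is the
    number of integers ``t`` whose line intersects the square.
    """
    omega = np.asarray(omega, dtype=float).reshape(-1)
    d = np.asarray(d, dtype=float).reshape(-1)
    corners = np.array([[0.0, 0.0], [l, 0.0], [0.0, l], [l, l]])
    proj = (corners - d) @ omega
    lo, hi = proj.min(), proj.max()
    return int(np.floor(hi / (2 * np.pi)) - np.ceil(lo / (2 * np.pi)) + 1)


def band_count_probability(
    h: float, j: int, l: float, n_draws: int = 10_000, seed: int = 0, corner_user: bool = True
) -> float:
    """Monte-Carlo ``P(band count >= j)`` for ``w ~ N(0, h^-2 I)``.

    With the user at a corner of the inscribed square (the worst case the
    bound protects), this estimates the probability that at least ``j``
    bands cross the area.  At ``h = max_bandwidth(gamma, j, l)`` it should
    be at least ``1 - C(gamma)`` with ``C`` the chi-squared CDF (2 df).
    """
    rng = np.random.default_rng(seed)
    omegas = rng.standard_normal((n_draws, 2)) / h
    d = np.zeros(2) if corner_user else np.full(2, l / 2.0)
    counts = np.fromiter(
        (count_bands_in_square(w, l, d) for w in omegas), dtype=int, count=n_draws
    )
    return float(np.mean(counts >= j))


def band_guarantee_level(gamma: float) -> float:
    """The probability level ``1 - C(gamma)`` of the band-count guarantee."""
    return float(1.0 - stats.chi2.cdf(gamma, df=2))
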