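"""Utility metric, bandwidth heuristic, and the privacy–utility sweep.

Utility is the Spearman rank correlation between an estimated density
surface and a reference surface over all grid nodes — for synthetic data
the known mixture density, for real data the fully pooled exact-KDE
surface (the best any privacy-preserving estimator can hope to match).
Privacy is the system score: the mean, over users, of the maxima-attack
localization error on each user's individual response.

``tradeoff_sweep`` reproduces the trade-off experiment: for every
(method, parameter, N, seed) cell it generates data, builds the estimate,
and records utility and privacy.  RFF is swept over the feature count B,
the GeoInd baseline over its epsilon, and the exact-KDE / 0-feature
baselines anchor the two ends of the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .adversary import (
    privacy_score_system,
    privacy_score_user,
    zero_feature_score,
)
from .geoind import GeoIndParams, geoind_surface
from .grid import GridSpec, Surface
from .kernels import user_basis
from .mixtures import builtin_mixture, default_grid, mixture_density, sample_mixture
from .protocol import federated_exact_surface, federated_rff_surface, user_surface_exact, user_surface_rff

__all__ = [
    "spearman",
    "select_bandwidth",
    "TradeoffRecord",
    "SweepConfig",
    "tradeoff_sweep",
    "gain_per_cost",
    "rff_privacy_score",
    "exact_privacy_score",
    "zero_privacy_score",
    "geoind_privacy_score",
]


def spearman(a: Surface, b: Surface) -> float:
    """Spearman rank correlation between two surfaces on the same grid.

    Ties get average ranks.  A constant input surface has no rank ordering;
    that case raises ``ValueError``.
    """
    if a.grid != b.grid:
        raise ValueError("surfaces must share one GridSpec")
    x, y = a.flat, b.flat
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant surface")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def select_bandwidth(points, k: int = 200, fraction: float = 0.1, rng=None) -> float:
    """k-NN bandwidth heuristic: mean k-th nearest-neighbor distance.

    A fraction of the data (default 10%) is subsampled without replacement;
    for each selected point the distance to its k-th nearest neighbor
    *within the subsample* (self excluded) is found, and the mean is
    returned.  ``k = 200`` suits the synthetic populations here (500 is a
    better default for large real check-in datasets).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if rng is None:
        rng = np.random.default_rng()
    m = int(np.ceil(fraction * n))
    if m <= k:
        raise ValueError(f"subsample size {m} must exceed k={k}")
    idx = rng.choice(n, size=m, replace=False)
    sub = points[idx]
    tree = cKDTree(sub)
    dists, _ = tree.query(sub, k=k + 1)  # column 0 is the point itself
    return float(np.mean(dists[:, k]))


# ---------------------------------------------------------------------------
# per-method privacy scores (per-user attack, averaged)

def _maybe_subsample(n: int, subsample, rng):
    if subsample is None or subsample >= n:
        return np.arange(n)
    return rng.choice(n, size=subsample, replace=False)


def rff_privacy_score(
    points,
    grid: GridSpec,
    h: float,
    B: int,
    master_seed: int,
    h0: Optional[float] = None,
    epsilon_filter: float = 1.1,
    subsample: Optional[int] = None,
) -> float:
    """System privacy score when users answer with B random features.

    Attacks each user's own response surface (built from the same keyed
    bases the aggregation uses) and averages the per-user scores.
    ``subsample`` limits the attack to a random subset of users.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if h0 is None:
        h0 = h
    rng = np.random.default_rng(master_seed)
    idx = _maybe_subsample(points.shape[0], subsample, rng)
    reports = []
    for i in idx:
        basis = user_basis(master_seed, int(i), B, h0, dim=grid.dim)
        surf = user_surface_rff(points[i], basis, h, grid)
        reports.append(privacy_score_user(surf, points[i], epsilon_filter))
    return privacy_score_system(reports)


def exact_privacy_score(
    points,
    grid: GridSpec,
    h: float,
    epsilon_filter: float = 1.1,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> float:
    """System privacy score of exact federated KDE (the no-privacy baseline)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rng = np.random.default_rng(seed)
    idx = _maybe_subsample(points.shape[0], subsample, rng)
    reports = [
        privacy_score_user(user_surface_exact(points[i], grid, h), points[i], epsilon_filter)
        for i in idx
    ]
    return privacy_score_system(reports)


def zero_privacy_score(points, grid: GridSpec, subsample: Optional[int] = None, seed: int = 0) -> float:
    """System privacy score of the constant response (best-case bound)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rng = np.random.default_rng(seed)
    idx = _maybe_subsample(points.shape[0], subsample, rng)
    return float(np.mean([zero_feature_score(grid, points[i]) for i in idx]))


def geoind_privacy_score(
    true_points,
    noisy_points,
    grid: GridSpec,
    h: float,
    epsilon_filter: float = 1.1,
    subsample: Optional[int] = None,
    seed: int = 0,
) -> float:
    """System privacy score of the GeoInd baseline.

    The server sees the exact surface of each *perturbed* location; the
    attack error is measured against the *true* location.
    """
    true_points = np.atleast_2d(np.asarray(true_points, dtype=float))
    noisy_points = np.atleast_2d(np.asarray(noisy_points, dtype=float))
    rng = np.random.default_rng(seed)
    idx = _maybe_subsample(true_points.shape[0], subsample, rng)
    reports = [
        privacy_score_user(
            user_surface_exact(noisy_points[i], grid, h), true_points[i], epsilon_filter
        )
        for i in idx
    ]
    return privacy_score_system(reports)


# ---------------------------------------------------------------------------
# the sweep

@dataclass
class TradeoffRecord:
    """One cell of the privacy–utility sweep."""

    method: str  # rff | geoind | exact | zero
    N: int
    seed: int
    h: float
    utility: Optional[float]
    privacy: float
    B: Optional[int] = None
    epsilon: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SweepConfig:
    """Specification of a trade-off sweep.

    ``h=None`` selects the bandwidth per dataset with the k-NN heuristic.
    ``reference`` chooses the utility ground truth: ``"truth"`` (the known
    mixture density) or ``"exact"`` (the pooled exact-KDE surface, the
    real-data convention).  ``privacy_subsample`` caps the number of users
    attacked per cell (None attacks all).
    """

    mixture: str = "grid9"
    N_list: Sequence[int] = (1000, 5000, 10000, 20000)
    B_list: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 50)
    epsilon_list: Sequence[float] = (0.6, 0.7, 0.8, 1.0, 3.0, 5.0, 10.0)
    h: Optional[float] = 0.55
    grid: Optional[GridSpec] = None
    seeds: Sequence[int] = tuple(range(10))
    reference: str = "truth"
    methods: Sequence[str] = ("rff", "geoind", "exact", "zero")
    knn_k: int = 200
    knn_fraction: float = 0.1
    epsilon_filter: float = 1.1
    privacy_subsample: Optional[int] = None

    def resolved_grid(self) -> GridSpec:
        return self.grid if self.grid is not None else default_grid(self.mixture)


def tradeoff_sweep(config: SweepConfig) -> List[TradeoffRecord]:
    """Run the full sweep; one record per (method, parameter, N, seed).

    Deterministic per seed: data, bases, and GeoInd noise all derive from
    the cell's seed, independent of execution order.
    """
    for m in config.methods:
        if m not in ("rff", "geoind", "exact", "zero"):
            raise ValueError(f"unknown method {m!r}")
    if config.reference not in ("truth", "exact"):
        raise ValueError("reference must be 'truth' or 'exact'")
    spec = builtin_mixture(config.mixture)
    grid = config.resolved_grid()
    truth = mixture_density(spec, grid) if config.reference == "truth" else None

    records: List[TradeoffRecord] = []
    for N in config.N_list:
        for seed in config.seeds:
            rng = np.random.default_rng(seed)
            data = sample_mixture(spec, N, rng)
            if config.h is None:
                h = select_bandwidth(
                    data, k=config.knn_k, fraction=config.knn_fraction,
                    rng=np.random.default_rng(seed + 1),
                )
            else:
                h = config.h
            exact_surf = federated_exact_surface(data, grid, h)
            reference = truth if truth is not None else exact_surf

            if "exact" in config.methods:
                records.append(TradeoffRecord(
                    method="exact", N=N, seed=seed, h=h,
                    utility=spearman(exact_surf, reference),
                    privacy=exact_privacy_score(
                        data, grid, h, config.epsilon_filter,
                        subsample=config.privacy_subsample, seed=seed,
                    ),
                ))
            if "zero" in config.methods:
                records.append(TradeoffRecord(
                    method="zero", N=N, seed=seed, h=h,
                    utility=None,  # a constant surface has no rank ordering
                    privacy=zero_privacy_score(
                        data, grid, subsample=config.privacy_subsample, seed=seed
                    ),
                ))
            if "rff" in config.methods:
                for B in config.B_list:
                    surf = federated_rff_surface(data, grid, h, B, master_seed=seed)
                    records.append(TradeoffRecord(
                        method="rff", N=N, seed=seed, h=h, B=B,
                        utility=spearman(surf, reference),
                        privacy=rff_privacy_score(
                            data, grid, h, B, master_seed=seed,
                            epsilon_filter=config.epsilon_filter,
                            subsample=config.privacy_subsample,
                        ),
                    ))
            if "geoind" in config.methods and grid.dim == 2:
                for eps in config.epsilon_list:
                    params = GeoIndParams(epsilon=eps, seed=seed)
                    surf, noisy = geoind_surface(data, params, grid, h)
                    records.append(TradeoffRecord(
                        method="geoind", N=N, seed=seed, h=h, epsilon=eps,
                        utility=spearman(surf, reference),
                        privacy=geoind_privacy_score(
                            data, noisy, grid, h, config.epsilon_filter,
                            subsample=config.privacy_subsample, seed=seed,
                        ),
                    ))
    return records


def gain_per_cost(records: Sequence[TradeoffRecord]):
    """Estimation-performance gain per unit privacy cost of extra features.

    For RFF records at a single N: gain(B) = utility(B) - utility(1);
    cost(B) = Z(1) - Z(B) (privacy scores fall as B rises, so the cost of
    the extra features is positive).  Returns ``[(B, gain/cost), ...]`` for
    B > 1, with medians over seeds; a zero cost yields ``inf`` (positive
    gain) or ``nan`` (no gain), never an exception.
    """
    rff = [r for r in records if r.method == "rff"]
    if not rff:
        raise ValueError("no rff records")
    ns = {r.N for r in rff}
    if len(ns) != 1:
        raise ValueError("gain_per_cost expects records at a single N")
    bs = sorted({r.B for r in rff})
    if 1 not in bs:
        raise ValueError("records must include the B = 1 baseline")

    def med(B, attr):
        return float(np.median([getattr(r, attr) for r in rff if r.B == B]))

    u1, z1 = med(1, "utility"), med(1, "privacy")
    out = []
    for B in bs:
        if B == 1:
            continue
        gain = med(B, "utility") - u1
        cost = z1 - med(B, "privacy")
        if cost == 0:
            ratio = np.inf if gain > 0 else np.nan
        else:
            ratio = gain / cost
        out.append((B, float(ratio)))
    return out
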