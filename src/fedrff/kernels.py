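"""Gaussian kernel and random Fourier feature (RFF) mathematics.

By Bochner's theorem the (unnormalized) Gaussian kernel
``k_h(x, y) = exp(-||x - y||^2 / (2 h^2))`` is the expectation of
``cos(w^T (x - y))`` over frequencies ``w ~ N(0, h^-2 I)``.  Averaging that
cosine over a handful of frozen random frequencies gives an unbiased
Monte-Carlo approximation of the kernel — and, crucially for privacy, each
cosine feature is spatially delocalized: its level sets are parallel bands
repeating across the whole plane.

A user draws frequencies once at a base bandwidth ``h0`` and never redraws
them; queries at other bandwidths are answered by rescaling the stored
frequencies by ``h0 / h`` (which maps ``N(0, h0^-2 I)`` draws exactly onto
``N(0, h^-2 I)``).  :class:`RFFBasis` enforces that frozen-frequency
contract: its frequency matrix is immutable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "gaussian_kernel",
    "RFFBasis",
    "sample_frequencies",
    "user_basis",
    "rescale_frequencies",
    "rff_projection",
]


def _as_points(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} vs {y.shape[-1]}")
    return x, y


def gaussian_kernel(x, y, h: float, normalized: bool = False):
    """Gaussian kernel ``exp(-||x - y||^2 / (2 h^2))``.

    ``x`` and ``y`` are points of shape ``(..., dim)``; broadcasting over
    leading axes is supported so a single location can be evaluated against a
    whole grid at once.  With ``normalized=True`` the value is divided by
    ``(2 pi h^2)^(dim/2)`` so that it integrates to one (useful when
    comparing against true densities; the protocol itself uses the
    unnormalized form, whose per-user surface peaks at 1).
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    x, y = _as_points(x, y)
    sq = np.sum((x - y) ** 2, axis=-1)
    val = np.exp(-sq / (2.0 * h * h))
    if normalized:
        dim = x.shape[-1]
        val = val / (2.0 * np.pi * h * h) ** (dim / 2.0)
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class RFFBasis:
    """A user's frozen random-feature frequencies.

    Attributes
    ----------
    h0 : float
        Base bandwidth at which the ``B`` frequency rows were drawn
        i.i.d. from ``N(0, h0^-2 I)``.
    omegas : ndarray, shape (B, dim)
        Frequency vectors; write-protected (never redrawn between queries).
    seed : int or None
        Seed the rows were drawn with, for provenance.
    """

    h0: float
    omegas: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self):
        if self.h0 <= 0:
            raise ValueError("h0 must be positive")
        om = np.atleast_2d(np.asarray(self.omegas, dtype=float)).copy()
        if om.shape[0] < 1:
            raise ValueError("basis needs at least one frequency vector")
        om.setflags(write=False)
        object.__setattr__(self, "omegas", om)

    @property
    def B(self) -> int:
        return self.omegas.shape[0]

    @property
    def dim(self) -> int:
        return self.omegas.shape[1]


def sample_frequencies(B: int, h0: float, dim: int = 2, seed=0) -> RFFBasis:
    """Draw ``B`` frequency vectors i.i.d. from ``N(0, h0^-2 I)``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; the draw is
    reproducible given the seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(seed)
    omegas = rng.standard_normal((B, dim)) / h0
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return RFFBasis(h0=h0, omegas=omegas, seed=stored_seed)


def user_basis(master_seed: int, user_index: int, B: int, h0: float, dim: int = 2) -> RFFBasis:
    """Basis for one user, derived from a master seed.

    Each user's frequencies come from an independent substream keyed by the
    user index, so any user's basis (and hence surface) is reproducible
    without iterating over the other users.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(int(user_index),))
    basis = sample_frequencies(B, h0, dim=dim, seed=ss)
    return RFFBasis(h0=basis.h0, omegas=basis.omegas, seed=int(master_seed))


def rescale_frequencies(basis: RFFBasis, h: float) -> np.ndarray:
    """Effective frequencies for a query at bandwidth ``h``.

    Returns ``(h0 / h) * omegas``: row directions are unchanged, only the
    wavelength of every feature band changes.  Rescaled rows are distributed
    exactly ``N(0, h^-2 I)``.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    return (basis.h0 / h) * basis.omegas


def rff_projection(basis: RFFBasis, h: float, d, g):
    """Average feature projection ``(1/B) sum_b cos(w_b^T (g - d))``.

    ``d`` is the user's location; ``g`` may be a single query point or an
    array of shape ``(..., dim)``.  Values lie in ``[-1, 1]``, equal 1 when
    ``g = d``, and depend on ``g`` and ``d`` only through ``g - d``.
    """
    d, g = _as_points(d, g)
    if basis.dim != d.shape[-1]:
        raise ValueError(f"dimension mismatch: basis {basis.dim} vs point {d.shape[-1]}")
    om = rescale_frequencies(basis, h)  # (B, dim)
    args = (g - d) @ om.T  # (..., B)
    val = np.mean(np.cos(args), axis=-1)
    return val if np.ndim(val) else float(val)
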