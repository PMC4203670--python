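"""Halton-based quasi-random standard-normal draws with antithetic mirroring.

Simulated likelihoods for mixed models average a conditional likelihood over
R draws from the mixing distribution.  The draws here are built from Halton
sequences (one prime base per mixing dimension), optionally made symmetric
about zero by antithetic mirroring:

* ``none``     -- conventional Halton draws (asymmetric in every dimension);
* ``one_dim``  -- each base point paired with its single global complement;
* ``full``     -- each base point paired with all ``2**n - 1`` coordinate
  complements, so the draw set for every individual is exactly closed under
  every coordinate-wise sign flip.

Full antithetics require the per-individual draw count R to be a multiple of
``2**n``; one-dimensional antithetics require an even R.  Each symmetric set
of mirrors belongs to one individual only — symmetry across individuals would
not make the per-individual panel likelihood symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import ndtri

__all__ = [
    "CANONICAL_PRIMES",
    "DrawConfig",
    "UnitDrawSet",
    "NormalDrawSet",
    "radical_inverse",
    "halton_sequence",
    "unit_to_normal",
    "make_full_antithetic",
    "make_one_dim_antithetic",
    "build_unit_draws",
    "build_draws",
    "skewness_coefficient",
]

#: First 25 primes, used when dimensions are assigned primes "canonically".
CANONICAL_PRIMES: tuple[int, ...] = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
    53, 59, 61, 67, 71, 73, 79, 83, 89, 97,
)

ANTITHETIC_MODES = ("none", "one_dim", "full")


def _is_prime(b: int) -> bool:
    if b < 2:
        return False
    if b < 4:
        return True
    if b % 2 == 0:
        return False
    f = 3
    while f * f <= b:
        if b % f == 0:
            return False
        f += 2
    return True


@dataclass(frozen=True)
class DrawConfig:
    """Configuration of a quasi-random draw set.

    Parameters
    ----------
    n_dims
        Dimension n of the mixing distribution.
    primes
        One prime base per dimension, in dimension order.  The prime-to-
        dimension assignment is part of the model: restricted models must
        keep it (see :func:`antimix.inference.reduce_draw_config`).
    draws_per_individual
        R, the number of draws per individual.  Must be a multiple of
        ``2**n_dims`` under ``full`` antithetics and even under ``one_dim``.
    n_individuals
        I, the number of individuals the draws serve.
    drop
        Number of initial Halton elements discarded per dimension before any
        point is used (the leading run of a Halton sequence is strongly
        correlated across bases).
    antithetic_mode
        ``"none"``, ``"one_dim"`` or ``"full"``.
    dim_names
        Label of the mixed parameter each dimension serves; defaults to
        ``dim_1 .. dim_n``.
    seed
        Recorded for provenance; Halton construction itself is deterministic
        and seed-free.
    """

    n_dims: int
    primes: tuple[int, ...]
    draws_per_individual: int
    n_individuals: int
    drop: int = 10
    antithetic_mode: str = "none"
    dim_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be a positive integer")
        primes = tuple(int(p) for p in self.primes)
        if len(primes) != self.n_dims:
            raise ValueError(
                f"need {self.n_dims} primes, got {len(primes)}"
            )
        for p in primes:
            if not _is_prime(p):
                raise ValueError(f"invalid Halton base {p}: not a prime >= 2")
        if len(set(primes)) != len(primes):
            raise ValueError("primes must be pairwise distinct")
        object.__setattr__(self, "primes", primes)
        if self.draws_per_individual < 1:
            raise ValueError("draws_per_individual must be positive")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.drop < 0:
            raise ValueError("drop must be non-negative")
        if self.antithetic_mode not in ANTITHETIC_MODES:
            raise ValueError(
                f"antithetic_mode must be one of {ANTITHETIC_MODES}"
            )
        R = self.draws_per_individual
        if self.antithetic_mode == "full":
            block = 2 ** self.n_dims
            if R % block:
                lo = (R // block) * block
                hi = lo + block
                raise ValueError(
                    f"full antithetics in {self.n_dims} dimensions need R to "
                    f"be a multiple of 2^{self.n_dims} = {block}; R={R} is "
                    f"not (nearest valid values: {lo or block} and {hi})"
                )
        elif self.antithetic_mode == "one_dim" and R % 2:
            raise ValueError(
                f"one-dimensional antithetics need an even R; R={R} is odd "
                f"(nearest valid values: {max(R - 1, 2)} and {R + 1})"
            )
        names = tuple(self.dim_names)
        if not names:
            names = tuple(f"dim_{k + 1}" for k in range(self.n_dims))
        if len(names) != self.n_dims or len(set(names)) != len(names):
            raise ValueError("dim_names must be n_dims distinct labels")
        object.__setattr__(self, "dim_names", names)

    @property
    def mirror_block(self) -> int:
        """Number of points in one antithetic set (1, 2 or ``2**n``)."""
        if self.antithetic_mode == "full":
            return 2 ** self.n_dims
        if self.antithetic_mode == "one_dim":
            return 2
        return 1

    def with_mode(self, mode: str) -> "DrawConfig":
        return replace(self, antithetic_mode=mode)


@dataclass(frozen=True)
class UnitDrawSet:
    """I x R x n points strictly inside the open unit cube."""

    points: np.ndarray
    config: DrawConfig

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        c = self.config
        shape = (c.n_individuals, c.draws_per_individual, c.n_dims)
        if pts.shape != shape:
            raise ValueError(f"points shape {pts.shape} != {shape}")
        if not ((pts > 0.0).all() and (pts < 1.0).all()):
            raise ValueError("unit draws must lie strictly inside (0, 1)")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class NormalDrawSet:
    """I x R x n standard-normal quasi-random points."""

    points: np.ndarray
    config: DrawConfig

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        c = self.config
        shape = (c.n_individuals, c.draws_per_individual, c.n_dims)
        if pts.shape != shape:
            raise ValueError(f"points shape {pts.shape} != {shape}")
        if not np.isfinite(pts).all():
            raise ValueError("normal draws must be finite")
        object.__setattr__(self, "points", pts)


def radical_inverse(index: int, base: int) -> float:
    """Reverse ``index``'s base-``base`` digits about the radix point.

    ``radical_inverse(5, 3)`` reads 5 = (1 2) in base 3 and returns
    0.21 (base 3) = 2/3 + 1/9 = 7/9.  The result is always in (0, 1) for
    ``index >= 1`` and is exactly representable as k / base**m.
    """
    if not _is_prime(base):
        raise ValueError(f"invalid Halton base {base}: not a prime >= 2")
    if index < 1:
        raise ValueError("index must be >= 1")
    inv = 0.0
    f = 1.0 / base
    i = int(index)
    while i > 0:
        inv += (i % base) * f
        i //= base
        f /= base
    return inv


def _radical_inverse_array(indices: np.ndarray, base: int) -> np.ndarray:
    # vectorised digit peel; exact while base**m stays within float precision
    idx = np.asarray(indices, dtype=np.int64).copy()
    out = np.zeros(idx.shape, dtype=float)
    f = 1.0 / base
    while idx.any():
        out += (idx % base) * f
        idx //= base
        f /= base
    return out


def halton_sequence(base: int, count: int, drop: int = 0) -> np.ndarray:
    """Elements ``drop+1 .. drop+count`` of the base-``base`` Halton sequence."""
    if not _is_prime(base):
        raise ValueError(f"invalid Halton base {base}: not a prime >= 2")
    if count < 1:
        raise ValueError("count must be >= 1")
    if drop < 0:
        raise ValueError("drop must be non-negative")
    return _radical_inverse_array(np.arange(drop + 1, drop + count + 1), base)


def unit_to_normal(u):
    """Standard-normal quantile of ``u``; antisymmetric about u = 1/2."""
    u = np.asarray(u, dtype=float)
    if ((u <= 0.0) | (u >= 1.0)).any():
        raise ValueError("unit_to_normal requires 0 < u < 1 (finite quantile)")
    z = ndtri(u)
    return float(z) if z.ndim == 0 else z


def _sign_masks(n: int) -> np.ndarray:
    """(2**n, n) array of +-1; row m flips dimension k iff bit k of m is set."""
    masks = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
    return 1.0 - 2.0 * (masks & 1)


def make_full_antithetic(base_points: np.ndarray) -> np.ndarray:
    """Expand each of M base points into its 2**n coordinate-complement set.

    Output row ``m * 2**n + mask`` is base point ``m`` with coordinate k
    replaced by its complement 1 - d_k wherever bit k of ``mask`` is set;
    mask 0 is the base point itself.
    """
    pts = np.asarray(base_points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("base_points must be an M x n array")
    if not ((pts > 0.0).all() and (pts < 1.0).all()):
        raise ValueError("base points must lie strictly inside (0, 1)")
    m, n = pts.shape
    signs = _sign_masks(n)  # (2**n, n)
    flip = signs < 0
    out = np.where(flip[None, :, :], 1.0 - pts[:, None, :], pts[:, None, :])
    return out.reshape(m * 2 ** n, n)


def make_one_dim_antithetic(base_points: np.ndarray) -> np.ndarray:
    """Pair each base point with its single global complement ``1 - d``."""
    pts = np.asarray(base_points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("base_points must be an M x n array")
    if not ((pts > 0.0).all() and (pts < 1.0).all()):
        raise ValueError("base points must lie strictly inside (0, 1)")
    m, n = pts.shape
    out = np.empty((m, 2, n), dtype=float)
    out[:, 0, :] = pts
    out[:, 1, :] = 1.0 - pts
    return out.reshape(2 * m, n)


def _base_unit_points(config: DrawConfig) -> np.ndarray:
    """(I, M, n) Halton base points, M = R / mirror_block, contiguous blocks
    of one continuous stream per dimension assigned to each individual."""
    c = config
    m = c.draws_per_individual // c.mirror_block
    cols = [
        halton_sequence(p, c.n_individuals * m, c.drop).reshape(
            c.n_individuals, m
        )
        for p in c.primes
    ]
    return np.stack(cols, axis=-1)


def build_unit_draws(config: DrawConfig) -> UnitDrawSet:
    """Unit-cube draw set, with antithetic mirrors taken in unit space."""
    c = config
    base = _base_unit_points(c)  # (I, M, n)
    i, m, n = base.shape
    if c.antithetic_mode == "none":
        pts = base
    elif c.antithetic_mode == "one_dim":
        pts = make_one_dim_antithetic(base.reshape(i * m, n)).reshape(
            i, 2 * m, n
        )
    else:
        pts = make_full_antithetic(base.reshape(i * m, n)).reshape(
            i, m * 2 ** n, n
        )
    return UnitDrawSet(points=pts, config=c)


def build_draws(config: DrawConfig) -> NormalDrawSet:
    """Standard-normal draw set per :class:`DrawConfig`.

    Antithetic mirrors are applied as sign flips of the normal-mapped base
    points — identical to complementing in unit space, since the normal
    quantile satisfies z(1-u) = -z(u), but exactly symmetric in floating
    point, so every antithetic set cancels and permutes bit-for-bit under
    sign flips.
    """
    c = config
    zbase = ndtri(_base_unit_points(c))  # (I, M, n)
    i, m, n = zbase.shape
    if c.antithetic_mode == "none":
        pts = zbase
    elif c.antithetic_mode == "one_dim":
        pts = np.stack([zbase, -zbase], axis=2).reshape(i, 2 * m, n)
    else:
        signs = _sign_masks(n)  # (2**n, n)
        pts = (zbase[:, :, None, :] * signs[None, None, :, :]).reshape(
            i, m * 2 ** n, n
        )
    return NormalDrawSet(points=pts, config=c)


def skewness_coefficient(draws: NormalDrawSet, dim: int) -> float:
    """Standardised third central moment of one dimension's pooled draws."""
    x = np.asarray(draws.points)[:, :, dim].ravel()
    if x.size < 3:
        raise ValueError("skewness needs at least 3 draws")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0.0:
        raise ValueError("skewness undefined for zero-variance draws")
    return float(np.mean(xc**3) / m2**1.5)
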