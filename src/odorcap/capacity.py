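"""Capacity and counting arguments: sphere packing, coloring bounds, grids.

All subset combinatorics use exact big-integer arithmetic; floating point
enters only for reporting (log10, interpolated counts) and for the
Monte-Carlo ring capacity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil, comb, isqrt, log10
from typing import Callable

import numpy as np

from . import models, protocol
from .errors import ConfigurationError, EstimationError
from .mixtures import ModelKind

__all__ = [
    "SphereCountQuery",
    "SphereCountResult",
    "ball_volume",
    "sphere_count",
    "min_percepts_for_criterion",
    "grid_percept_count",
    "ring_capacity",
    "ring_separation_at_criterion",
    "log10_subset_count",
    "critical_mixture_size_color",
]


@dataclass(frozen=True)
class SphereCountQuery:
    """How many diameter-D regions fit among the N-subsets of C primaries."""

    C: int
    N: int
    D: int

    def __post_init__(self) -> None:
        if not (1 <= self.N <= self.C):
            raise ConfigurationError("need 1 <= N <= C")
        if not (1 <= self.D <= 2 * self.N):
            raise ConfigurationError("need 1 <= D <= 2N")


@dataclass(frozen=True)
class SphereCountResult:
    """Exact packing counts at the bracketing integer radii.

    For even D the two brackets coincide and ``S`` is exact; for odd D the
    radius D/2 is non-integral, so the exact counts at radii (D-1)/2 and
    (D+1)/2 are both reported together with their geometric mean ``S``
    (log-linear interpolation).
    """

    query: SphereCountQuery
    S_floor: int
    S_ceil: int
    S: float

    @property
    def exact(self) -> bool:
        return self.S_floor == self.S_ceil

    @property
    def log10_S(self) -> float:
        return float(np.log10(self.S))

    def as_dict(self) -> dict:
        return {
            "C": self.query.C,
            "N": self.query.N,
            "D": self.query.D,
            "S_floor": str(self.S_floor),
            "S_ceil": str(self.S_ceil),
            "S": self.S,
            "log10_S": self.log10_S,
            "exact": self.exact,
        }


def ball_volume(C: int, N: int, radius: int) -> int:
    """Number of N-subsets within ``radius`` component replacements of a fixed one.

    Replacing R of the N members with R of the C - N outsiders gives
    C(N, R) * C(C - N, R) subsets at replacement distance exactly R.
    """
    return sum(comb(N, R) * comb(C - N, R) for R in range(radius + 1))


def _count_at_radius(C: int, N: int, radius: int) -> int:
    return comb(C, N) // ball_volume(C, N, radius)


def sphere_count(query: SphereCountQuery) -> SphereCountResult:
    """Hamming-bound packing count: total N-subsets over the radius-D/2 ball.

    D = 1 means every subset is its own region, S = C(C, N).  Odd D >= 3 is
    bracketed by the exact counts at the two adjacent integer radii and
    summarized by their geometric mean.
    """
    C, N, D = query.C, query.N, query.D
    if D == 1:
        s = comb(C, N)
        return SphereCountResult(query=query, S_floor=s, S_ceil=s, S=float(s))
    if D % 2 == 0:
        s = _count_at_radius(C, N, D // 2)
        return SphereCountResult(query=query, S_floor=s, S_ceil=s, S=float(s))
    s_lo = _count_at_radius(C, N, (D + 1) // 2)  # larger radius -> smaller count
    s_hi = _count_at_radius(C, N, (D - 1) // 2)
    geo = float(isqrt(s_lo * s_hi)) if s_lo > 0 else 0.0
    return SphereCountResult(query=query, S_floor=s_lo, S_ceil=s_hi, S=geo)


def _as_fraction(x: float) -> Fraction:
    # recover the intended decimal value of a float parameter exactly
    return Fraction(x).limit_denominator(10**12)


def min_percepts_for_criterion(q: float) -> int:
    """Fewest equal-frequency percept labels making each sphere differ from
    a fraction >= q of its neighbors: k = ceil(1 / (1 - q)).

    With k equally frequent labels an alternating assignment distinguishes a
    sphere from (k - 1)/k of its neighbors, so (k - 1)/k >= q suffices.
    """
    if not (0 < q < 1):
        raise ConfigurationError("q must lie strictly between 0 and 1")
    qf = _as_fraction(q)
    return int(ceil(1 / (1 - qf)))


def grid_percept_count(jnd: float, dims: int) -> int:
    """floor(1/jnd) ** dims resolvable points in a unit cube of that many dims."""
    if jnd <= 0 or dims < 1:
        raise ConfigurationError("need jnd > 0 and dims >= 1")
    per_axis = int(1 / _as_fraction(jnd))
    return per_axis**dims


def log10_subset_count(C: int, N: int) -> int:
    """round(log10(C(C, N))) — the order of magnitude of the subset count."""
    if not (0 <= N <= C):
        raise ConfigurationError("need 0 <= N <= C")
    return int(round(log10(comb(C, N)))) if comb(C, N) > 0 else 0


# ---------------------------------------------------------------------------
# Monte-Carlo capacities
# ---------------------------------------------------------------------------


def _p_correct_ring(delta: float, sigma: float, z: np.ndarray) -> float:
    """Single-trial odd-man-out accuracy for ring percepts ``delta`` apart."""
    n = sigma * z
    x1, x2 = n[:, 0], n[:, 1]
    x3 = delta + n[:, 2]
    d_dup = protocol.circular_distance(x1, x2)
    d_13 = protocol.circular_distance(x1, x3)
    d_23 = protocol.circular_distance(x2, x3)
    return float(np.mean((d_dup < d_13) & (d_dup < d_23)))


def ring_separation_at_criterion(
    sigma_ring: float,
    criterion: float = 0.5,
    n_mc: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Angular separation at which single-trial accuracy equals the criterion.

    Bisection with common random numbers; >= n_mc trials per evaluation.
    """
    if sigma_ring <= 0:
        raise ConfigurationError("sigma_ring must be > 0")
    if not (1.0 / 3.0 < criterion < 1.0):
        raise ConfigurationError("criterion must lie in (1/3, 1)")
    if rng is None:
        rng = np.random.default_rng()
    z = rng.standard_normal((int(n_mc), 3))
    lo, hi = 0.0, float(np.pi)
    if _p_correct_ring(hi, sigma_ring, z) < criterion:
        raise EstimationError(
            f"accuracy never reaches {criterion} even at separation pi "
            f"(sigma_ring={sigma_ring})"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _p_correct_ring(mid, sigma_ring, z) < criterion:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ring_capacity(
    sigma_ring: float,
    criterion: float = 0.5,
    n_mc: int = 200_000,
    rng: np.random.Generator | None = None,
) -> int:
    """Most equally spaced circle vectors with neighbors discriminable at the
    criterion: floor(2*pi / delta_50).

    If even diametrically opposed vectors fail the criterion (very large
    noise wrapping the circle), no two vectors are mutually discriminable
    and the capacity collapses to 1.
    """
    try:
        delta = ring_separation_at_criterion(sigma_ring, criterion, n_mc, rng)
    except EstimationError:
        return 1
    return int(2.0 * np.pi / delta)


def critical_mixture_size_color(
    jnd: float = 0.01,
    *,
    rng: np.random.Generator | None = None,
    sigma_rgb: float | None = None,
    C: int = 128,
    n_pairs: int = 20,
    n_trials: int = 26,
    n_replicates: int = 200,
    n_max: int = 127,
    level: float = 0.5,
) -> int:
    """Smallest mixture size N at which one unshared component no longer
    suffices: mean discriminability of (N, O=N-1) classes drops to <= level.

    Component norms scale as 1/N (equal-part mixing at fixed intensity), so
    the mixture separation from one swapped component shrinks with N while the
    calibrated noise stays fixed.  Binary search on N, each evaluation a
    reduced-replicate run of the odd-man-out protocol.
    """
    if rng is None:
        rng = np.random.default_rng()
    if sigma_rgb is None:
        sigma_rgb = models.calibrate_color_noise(jnd, rng=rng)
    noise = models.NoiseConfig(sigma_rgb=sigma_rgb, jnd=jnd)

    def mean_fraction(N: int) -> float:
        curve = protocol.discrimination_curve(
            ModelKind.COLOR,
            N=N,
            overlaps=[N - 1],
            C=C,
            n_pairs=n_pairs,
            n_trials=n_trials,
            n_replicates=n_replicates,
            noise=noise,
            rng=rng.spawn(1)[0],
            primary_norm=1.0 / N,
        )
        return float(curve.mean_fraction[0])

    lo, hi = 2, int(min(n_max, C - 1))
    if mean_fraction(lo) <= level:
        raise EstimationError(f"already below {level} at N={lo}")
    if mean_fraction(hi) > level:
        raise EstimationError(f"still above {level} at N={hi}; raise n_max")
    while hi - lo > 1:  # invariant: f(lo) > level >= f(hi)
        mid = (lo + hi) // 2
        if mean_fraction(mid) > level:
            lo = mid
        else:
            hi = mid
    return hi
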