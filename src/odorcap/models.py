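"""The three perceptual encoding models and their noise.

* microbe — sums +-1 component values and emits one of three categories;
  deterministic, so discrimination is a pure category comparison.
* color — mixtures add linearly in a 3-D RGB cube; iid Gaussian noise on each
  coordinate, with the noise SD calibrated so that a stated Euclidean
  separation (the JND) is just discriminable in the odd-man-out test.
* ring — components are unit vectors on a circle; a mixture maps to the angle
  of their normalized sum (discarding intensity), and Gaussian noise is added
  to the angle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, ConfigurationError, DegenerateMixtureError, InvalidMixtureError

__all__ = [
    "MicrobeCategory",
    "NoiseConfig",
    "microbe_category",
    "microbe_category_codes",
    "color_mixture_vector",
    "ring_mixture_angle",
    "perturb_ring",
    "perturb_color",
    "calibrate_color_noise",
]

TWO_PI = 2.0 * np.pi
DEGENERATE_NORM = 1e-12

#: category boundaries: sum > +2 -> yum, sum < -2 -> yuck, else meh
MICROBE_THRESHOLD = 2


class MicrobeCategory(Enum):
    YUM = 1
    MEH = 0
    YUCK = -1


def microbe_category(mixture_sum: int) -> MicrobeCategory:
    """Three-state response to the integer sum of +-1 component values.

    Boundaries are inclusive to MEH: sums of exactly +-2 read as MEH.
    """
    if mixture_sum > MICROBE_THRESHOLD:
        return MicrobeCategory.YUM
    if mixture_sum < -MICROBE_THRESHOLD:
        return MicrobeCategory.YUCK
    return MicrobeCategory.MEH


def microbe_category_codes(sums: np.ndarray) -> np.ndarray:
    """Vectorized category codes (+1 yum / 0 meh / -1 yuck)."""
    sums = np.asarray(sums)
    return np.where(sums > MICROBE_THRESHOLD, 1, np.where(sums < -MICROBE_THRESHOLD, -1, 0))


def color_mixture_vector(components: Sequence[np.ndarray]) -> np.ndarray:
    """Coordinate-wise sum of component RGB vectors; no renormalization."""
    arr = np.asarray(components, dtype=float)
    if arr.size == 0:
        raise InvalidMixtureError("a color mixture needs at least one component")
    return arr.reshape(-1, 3).sum(axis=0)


def ring_mixture_angle(components: Sequence[float]) -> float:
    """Angle of the vector sum of unit vectors at the component angles.

    Normalizing the sum to unit length discards intensity, so only the angle
    is returned.  A sum vector of (numerically) zero length has no angle.
    """
    angles = np.asarray(components, dtype=float)
    if angles.size == 0:
        raise InvalidMixtureError("a ring mixture needs at least one component")
    x = np.cos(angles).sum()
    y = np.sin(angles).sum()
    if np.hypot(x, y) <= DEGENERATE_NORM:
        raise DegenerateMixtureError("component unit vectors sum to zero")
    return float(np.arctan2(y, x) % TWO_PI)


def perturb_ring(angle, sigma_ring: float, rng: np.random.Generator):
    """Add Gaussian angular noise, reduced mod 2*pi.  Broadcasts over arrays."""
    angle = np.asarray(angle, dtype=float)
    noisy = (angle + sigma_ring * rng.standard_normal(angle.shape)) % TWO_PI
    return noisy if noisy.shape else float(noisy)


def perturb_color(vector, sigma_rgb: float, rng: np.random.Generator) -> np.ndarray:
    """Add iid Gaussian noise per coordinate; no clipping to the unit cube."""
    vector = np.asarray(vector, dtype=float)
    return vector + sigma_rgb * rng.standard_normal(vector.shape)


@dataclass(frozen=True)
class NoiseConfig:
    """Per-model perceptual noise parameters.

    ``sigma_rgb`` is usually obtained from :func:`calibrate_color_noise`; the
    microbe model is noiseless by construction.
    """

    sigma_ring: float = 0.4
    sigma_rgb: float | None = None
    jnd: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma_ring <= 0:
            raise ConfigurationError("sigma_ring must be > 0")
        if self.jnd <= 0:
            raise ConfigurationError("jnd must be > 0")
        if self.sigma_rgb is not None and self.sigma_rgb <= 0:
            raise ConfigurationError("sigma_rgb must be > 0")

    def with_calibrated_rgb(
        self, rng: np.random.Generator, **kwargs
    ) -> "NoiseConfig":
        sigma = calibrate_color_noise(self.jnd, rng=rng, **kwargs)
        return replace(self, sigma_rgb=sigma)


def _odd_man_out_correct_3d(
    separation: float, sigma: float, z: np.ndarray
) -> float:
    """Fraction of correct single odd-man-out trials in 3-D.

    ``z`` holds standard-normal draws of shape (n, 3, 3): per trial, noise for
    the two duplicate samples and the target sample.  Correct means the two
    duplicates are the closest pair.
    """
    n = sigma * z
    offset = np.array([separation, 0.0, 0.0])
    x1 = n[:, 0]
    x2 = n[:, 1]
    x3 = offset + n[:, 2]
    d_dup = np.linalg.norm(x1 - x2, axis=1)
    d_13 = np.linalg.norm(x1 - x3, axis=1)
    d_23 = np.linalg.norm(x2 - x3, axis=1)
    return float(np.mean((d_dup < d_13) & (d_dup < d_23)))


def _majority_equivalent_p(n_trials: int) -> float:
    """Single-trial accuracy at which the >50%-of-trials criterion is a coin flip."""

    def tail(p: float) -> float:
        return float(stats.binom.sf(n_trials // 2, n_trials, p))

    lo, hi = 1.0 / 3.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if tail(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_color_noise(
    jnd: float = 0.01,
    *,
    rng: np.random.Generator,
    rule: str = "single",
    n_mc: int = 200_000,
    tol: float = 0.005,
    n_trials: int = 26,
) -> float:
    """Find sigma_rgb so that separation ``jnd`` is just discriminable.

    ``rule='single'`` targets single-trial odd-man-out P(correct) = 0.5 (the
    default reading of "just discriminable"); ``rule='majority'`` instead
    targets the single-trial accuracy at which the >50%-of-``n_trials``
    majority criterion is met half the time.  Bisection on sigma with common
    random numbers; at least ``n_mc`` Monte-Carlo trials per evaluation.
    """
    if jnd <= 0:
        raise ConfigurationError("jnd must be > 0")
    if rule == "single":
        target = 0.5
    elif rule == "majority":
        target = _majority_equivalent_p(n_trials)
    else:
        raise ConfigurationError(f"unknown calibration rule: {rule!r}")

    z = rng.standard_normal((int(n_mc), 3, 3))
    lo, hi = jnd * 1e-3, jnd * 1e3
    if not (
        _odd_man_out_correct_3d(jnd, lo, z) > target > _odd_man_out_correct_3d(jnd, hi, z)
    ):
        raise CalibrationError("bisection bracket does not straddle the target")
    for _ in range(60):
        mid = np.sqrt(lo * hi)  # sigma spans decades; bisect in log space
        if _odd_man_out_correct_3d(jnd, mid, z) > target:
            lo = mid
        else:
            hi = mid
    sigma = float(np.sqrt(lo * hi))

    check = _odd_man_out_correct_3d(jnd, sigma, rng.standard_normal((int(n_mc), 3, 3)))
    if abs(check - target) > max(tol, 4.0 / np.sqrt(n_mc)):
        raise CalibrationError(
            f"calibrated sigma={sigma:.6g} gives P(correct)={check:.4f}, "
            f"target {target:.4f} +- {tol} (n_mc={n_mc})"
        )
    return sigma
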