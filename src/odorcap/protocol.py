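"""Odd-man-out discrimination protocol and discriminability-vs-overlap curves.

A trial presents three noisy percepts, two drawn from one mixture and one from
the other; the pair with the smallest perceptual distance is declared "same"
and the remaining sample "odd".  A mixture pair is discriminable when the odd
sample is identified correctly on more than half of the trials (14 or more of
26 by default).  Class-level discriminability is the fraction of pairs in an
(N, O) class that pass, and curves average that fraction over many replicate
designs with freshly drawn primaries.

The microbe model bypasses the trial machinery: its response is deterministic,
so a pair is discriminable iff the two category labels differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import models
from .errors import (
    InfeasibleDesignError,
    NoCriticalDistanceError,
    ProtocolError,
)
from .mixtures import (
    DEFAULT_C,
    DEFAULT_N_PAIRS,
    ModelKind,
    _color_unit_vectors,
    default_overlap_grid,
    draw_primaries,
)

__all__ = [
    "TrialRecord",
    "PairResult",
    "DiscriminationCurve",
    "CriticalDistance",
    "odd_man_out_trial",
    "pair_discriminability",
    "class_fraction",
    "discrimination_curve",
    "critical_distance",
    "majority_threshold",
    "circular_distance",
]

DEFAULT_N_TRIALS = 26


def majority_threshold(n_trials: int = DEFAULT_N_TRIALS) -> int:
    """Smallest correct count exceeding 50% of trials (14 for 26 trials)."""
    return n_trials // 2 + 1


def circular_distance(a, b):
    """Arc distance between angles, reduced to [0, pi]."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % (2.0 * np.pi)
    return np.minimum(d, 2.0 * np.pi - d)


@dataclass(frozen=True)
class TrialRecord:
    """One odd-man-out presentation: three noisy samples and the decision."""

    x_a: object
    x_b: object
    x_c: object
    target_position: int  # which of the three samples came from the odd mixture
    chosen_odd: int
    correct: bool


@dataclass(frozen=True)
class PairResult:
    n_trials: int
    n_correct: int
    discriminable: bool

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError("n_correct outside [0, n_trials]")


@dataclass(frozen=True)
class DiscriminationCurve:
    """Mean +- SD fraction of discriminable pairs per overlap, over replicates."""

    model_kind: ModelKind
    N: int
    overlaps: np.ndarray
    mean_fraction: np.ndarray
    sd_fraction: np.ndarray
    n_replicates: int
    #: optional per-pair correct fractions, shape (n_replicates, n_overlaps, n_pairs)
    pair_correct_fraction: np.ndarray | None = field(default=None, repr=False)


@dataclass(frozen=True)
class CriticalDistance:
    """Unshared-component separation at the criterion crossing of a curve."""

    D: float
    level: float = 0.5
    crossing_overlap: float | None = None

    @property
    def D_int(self) -> int:
        return int(round(self.D))


# ---------------------------------------------------------------------------
# scalar protocol operations (reference path; the curve engine is vectorized)
# ---------------------------------------------------------------------------


def _noisy_sample(model_kind: ModelKind, percept, noise: models.NoiseConfig, rng):
    if model_kind is ModelKind.COLOR:
        return models.perturb_color(percept, noise.sigma_rgb, rng)
    return models.perturb_ring(percept, noise.sigma_ring, rng)


def _distance(model_kind: ModelKind, x, y) -> float:
    if model_kind is ModelKind.COLOR:
        return float(np.linalg.norm(np.asarray(x) - np.asarray(y)))
    return float(circular_distance(x, y))


def odd_man_out_trial(
    model_kind: ModelKind | str,
    percept_a,
    percept_b,
    noise: models.NoiseConfig,
    rng: np.random.Generator,
) -> TrialRecord:
    """Run one three-sample trial on the noiseless percepts of a mixture pair.

    The duplicated mixture and the position of the odd sample are both
    re-randomized per trial.  Distance ties are broken uniformly at random.
    """
    model_kind = ModelKind.coerce(model_kind)
    if model_kind is ModelKind.MICROBE:
        raise ProtocolError("the microbe model uses a deterministic category comparison")
    dup, tgt = (percept_a, percept_b) if rng.integers(2) == 0 else (percept_b, percept_a)
    samples = [
        _noisy_sample(model_kind, dup, noise, rng),
        _noisy_sample(model_kind, dup, noise, rng),
        _noisy_sample(model_kind, tgt, noise, rng),
    ]
    order = rng.permutation(3)
    placed = [samples[i] for i in order]
    target_position = int(np.argmax(order == 2))
    pair_of = [(1, 2), (0, 2), (0, 1)]  # closest pair excluding each position
    dists = np.array(
        [_distance(model_kind, placed[i], placed[j]) for i, j in pair_of]
    )
    odd_candidates = np.flatnonzero(dists == dists.min())
    chosen_odd = int(rng.choice(odd_candidates))
    return TrialRecord(
        x_a=placed[0],
        x_b=placed[1],
        x_c=placed[2],
        target_position=target_position,
        chosen_odd=chosen_odd,
        correct=chosen_odd == target_position,
    )


def pair_discriminability(
    model_kind: ModelKind | str,
    percept_a,
    percept_b,
    noise: models.NoiseConfig | None = None,
    n_trials: int = DEFAULT_N_TRIALS,
    rng: np.random.Generator | None = None,
) -> PairResult:
    """26-trial majority verdict for color/ring; category comparison for microbe.

    Microbe percepts are the integer mixture sums.
    """
    model_kind = ModelKind.coerce(model_kind)
    if model_kind is ModelKind.MICROBE:
        different = models.microbe_category(percept_a) != models.microbe_category(percept_b)
        return PairResult(n_trials=1, n_correct=int(different), discriminable=different)
    n_correct = sum(
        odd_man_out_trial(model_kind, percept_a, percept_b, noise, rng).correct
        for _ in range(n_trials)
    )
    return PairResult(
        n_trials=n_trials,
        n_correct=n_correct,
        discriminable=n_correct >= majority_threshold(n_trials),
    )


def class_fraction(
    model_kind: ModelKind | str,
    percept_pairs,
    noise: models.NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    n_trials: int = DEFAULT_N_TRIALS,
) -> float:
    """Fraction of (percept_a, percept_b) pairs judged discriminable."""
    results = [
        pair_discriminability(model_kind, pa, pb, noise, n_trials, rng)
        for pa, pb in percept_pairs
    ]
    return float(np.mean([r.discriminable for r in results]))


# ---------------------------------------------------------------------------
# vectorized curve engine
# ---------------------------------------------------------------------------


def _ncorrect_batch(
    model_kind: ModelKind,
    percepts_a: np.ndarray,
    percepts_b: np.ndarray,
    noise: models.NoiseConfig,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correct-trial counts for a batch of pairs, (n_pairs,) ints.

    Vectorizes over pairs and trials; the duplicated mixture is re-randomized
    per trial and ties are broken uniformly at random (only reachable with
    degenerate noise).
    """
    n_pairs = len(percepts_a)
    swap = rng.random((n_pairs, n_trials)) < 0.5
    if model_kind is ModelKind.COLOR:
        sigma = noise.sigma_rgb
        pa = percepts_a[:, None, :]
        pb = percepts_b[:, None, :]
        dup = np.where(swap[:, :, None], pb, pa)
        tgt = np.where(swap[:, :, None], pa, pb)
        z = sigma * rng.standard_normal((n_pairs, n_trials, 3, 3))
        x1 = dup + z[:, :, 0]
        x2 = dup + z[:, :, 1]
        x3 = tgt + z[:, :, 2]
        d = np.stack(
            [
                np.linalg.norm(x1 - x2, axis=-1),
                np.linalg.norm(x1 - x3, axis=-1),
                np.linalg.norm(x2 - x3, axis=-1),
            ],
            axis=-1,
        )
    elif model_kind is ModelKind.RING:
        sigma = noise.sigma_ring
        pa = percepts_a[:, None]
        pb = percepts_b[:, None]
        dup = np.where(swap, pb, pa)
        tgt = np.where(swap, pa, pb)
        z = sigma * rng.standard_normal((n_pairs, n_trials, 3))
        x1 = dup + z[:, :, 0]
        x2 = dup + z[:, :, 1]
        x3 = tgt + z[:, :, 2]
        d = np.stack(
            [
                circular_distance(x1, x2),
                circular_distance(x1, x3),
                circular_distance(x2, x3),
            ],
            axis=-1,
        )
    else:  # pragma: no cover - guarded upstream
        raise ProtocolError("microbe model has no trial machinery")
    # the odd sample is correct iff the duplicate pair (index 0) is closest;
    # ties resolved uniformly by random keys
    ties = d == d.min(axis=-1, keepdims=True)
    winner = np.argmax(ties * rng.random(d.shape), axis=-1)
    return (winner == 0).sum(axis=1)


def _ring_percepts(
    angles: np.ndarray, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resultant angles and norms for rows of component indices."""
    a = angles[idx]
    x = np.cos(a).sum(axis=1)
    y = np.sin(a).sum(axis=1)
    return np.arctan2(y, x) % (2.0 * np.pi), np.hypot(x, y)


def _replicate_fractions(
    model_kind: ModelKind,
    N: int,
    overlaps: np.ndarray,
    C: int,
    n_pairs: int,
    n_trials: int,
    noise: models.NoiseConfig,
    rng: np.random.Generator,
    fresh_vectors: bool,
    primary_norm: float,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Class fractions (and per-pair correct fractions) for one replicate design."""
    n_cls = len(overlaps)
    fractions = np.empty(n_cls)
    pair_frac = None if model_kind is ModelKind.MICROBE else np.empty((n_cls, n_pairs))

    if fresh_vectors:
        # unbounded-dimensional color variant: every pair has its own vectors
        for i, O in enumerate(overlaps):
            k = 2 * N - O
            vecs = _color_unit_vectors(n_pairs * k, rng, primary_norm).reshape(
                n_pairs, k, 3
            )
            va = vecs[:, :N].sum(axis=1)
            vb = vecs[:, N - O : 2 * N - O].sum(axis=1)
            nc = _ncorrect_batch(model_kind, va, vb, noise, n_trials, rng)
            fractions[i] = np.mean(nc >= majority_threshold(n_trials))
            pair_frac[i] = nc / n_trials
        return fractions, pair_frac

    primaries = draw_primaries(model_kind, C, rng, color_norm=primary_norm)
    values = primaries.values
    # one random permutation row per pair; slices give exchangeable subsets
    keys = rng.random((n_cls * n_pairs, C))
    perm = np.argsort(keys, axis=1)
    thr = majority_threshold(n_trials)
    for i, O in enumerate(overlaps):
        idx = perm[i * n_pairs : (i + 1) * n_pairs]
        ia = idx[:, :N]
        ib = idx[:, N - O : 2 * N - O]
        if model_kind is ModelKind.MICROBE:
            ca = models.microbe_category_codes(values[ia].sum(axis=1))
            cb = models.microbe_category_codes(values[ib].sum(axis=1))
            fractions[i] = np.mean(ca != cb)
            continue
        if model_kind is ModelKind.COLOR:
            pa = values[ia].sum(axis=1)
            pb = values[ib].sum(axis=1)
        else:
            pa, norm_a = _ring_percepts(values, ia)
            pb, norm_b = _ring_percepts(values, ib)
            bad = np.flatnonzero(
                (norm_a <= models.DEGENERATE_NORM) | (norm_b <= models.DEGENERATE_NORM)
            )
            while bad.size:  # degenerate resultants are redrawn at design time
                redo = np.argsort(rng.random((bad.size, C)), axis=1)
                ia[bad] = redo[:, :N]
                ib[bad] = redo[:, N - O : 2 * N - O]
                pa, norm_a = _ring_percepts(values, ia)
                pb, norm_b = _ring_percepts(values, ib)
                bad = np.flatnonzero(
                    (norm_a <= models.DEGENERATE_NORM)
                    | (norm_b <= models.DEGENERATE_NORM)
                )
        nc = _ncorrect_batch(model_kind, pa, pb, noise, n_trials, rng)
        fractions[i] = np.mean(nc >= thr)
        pair_frac[i] = nc / n_trials
    return fractions, pair_frac


def discrimination_curve(
    model_kind: ModelKind | str,
    N: int = 30,
    overlaps=None,
    *,
    C: int = DEFAULT_C,
    n_pairs: int = DEFAULT_N_PAIRS,
    n_trials: int = DEFAULT_N_TRIALS,
    n_replicates: int = 1000,
    noise: models.NoiseConfig | None = None,
    rng: np.random.Generator | int | None = None,
    fresh_vectors: bool = False,
    primary_norm: float | None = None,
    collect_pair_stats: bool = False,
) -> DiscriminationCurve:
    """Mean +- SD discriminable fraction vs overlap over replicate designs.

    Each replicate redraws the primary pool and all mixture classes, runs the
    protocol, and records per-class fractions.  ``fresh_vectors=True`` (color
    only) draws each pair's component vectors fresh instead of from a pool.
    Replicates use spawned RNG substreams, so the curve is reproducible from
    a single seed.  Infeasible (N, O) classes are skipped with a warning.
    """
    model_kind = ModelKind.coerce(model_kind)
    if noise is None:
        noise = models.NoiseConfig()
    if model_kind is ModelKind.COLOR and not noise.sigma_rgb:
        raise ProtocolError("color protocol requires a calibrated sigma_rgb")
    if fresh_vectors and model_kind is not ModelKind.COLOR:
        raise ProtocolError("fresh_vectors is only defined for the color model")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if primary_norm is None:
        primary_norm = 1.0 / N
    if overlaps is None:
        overlaps = default_overlap_grid(N)
    overlaps = np.array(sorted(set(int(o) for o in overlaps)))
    if np.any(overlaps < 0) or np.any(overlaps > N):
        raise InfeasibleDesignError("overlaps must lie in [0, N]")
    if not fresh_vectors:
        feasible = 2 * N - overlaps <= C
        if not feasible.all():
            skipped = overlaps[~feasible].tolist()
            warnings.warn(
                f"skipping infeasible overlap classes {skipped} for C={C}, N={N}",
                stacklevel=2,
            )
            overlaps = overlaps[feasible]
    if overlaps.size == 0:
        raise InfeasibleDesignError("no feasible overlap classes")

    fractions = np.empty((n_replicates, len(overlaps)))
    pair_stats = (
        np.empty((n_replicates, len(overlaps), n_pairs))
        if collect_pair_stats and model_kind is not ModelKind.MICROBE
        else None
    )
    for r, child in enumerate(rng.spawn(n_replicates)):
        frac, pf = _replicate_fractions(
            model_kind,
            N,
            overlaps,
            C,
            n_pairs,
            n_trials,
            noise,
            child,
            fresh_vectors,
            primary_norm,
        )
        fractions[r] = frac
        if pair_stats is not None:
            pair_stats[r] = pf
    ddof = 1 if n_replicates > 1 else 0
    return DiscriminationCurve(
        model_kind=model_kind,
        N=N,
        overlaps=overlaps,
        mean_fraction=fractions.mean(axis=0),
        sd_fraction=fractions.std(axis=0, ddof=ddof),
        n_replicates=n_replicates,
        pair_correct_fraction=pair_stats,
    )


def critical_distance(curve: DiscriminationCurve, level: float = 0.5) -> CriticalDistance:
    """Unshared-component distance D at the curve's criterion crossing.

    Linear interpolation of mean fraction vs O at the first downward crossing;
    D = N - O*.  If the mean never falls below the level for any O <= N - 1,
    a single unshared component already suffices and D = 1 by convention.
    """
    O = np.asarray(curve.overlaps, dtype=float)
    m = np.asarray(curve.mean_fraction, dtype=float)
    if m[0] < level:
        raise NoCriticalDistanceError(
            f"curve starts below the {level:.0%} level at O={O[0]:g}"
        )
    head = m[O <= curve.N - 1]
    if head.size and head.min() >= level:
        return CriticalDistance(D=1.0, level=level, crossing_overlap=float(curve.N - 1))
    for i in range(len(O) - 1):
        if m[i] >= level > m[i + 1]:
            t = (m[i] - level) / (m[i] - m[i + 1])
            o_star = O[i] + t * (O[i + 1] - O[i])
            return CriticalDistance(
                D=float(curve.N - o_star), level=level, crossing_overlap=float(o_star)
            )
    raise NoCriticalDistanceError("no downward crossing found")  # pragma: no cover
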