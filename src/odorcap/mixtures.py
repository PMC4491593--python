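"""Synthetic stimulus designs: primary pools and overlap-controlled mixture pairs.

Two N-component mixtures with overlap ``O`` are built by drawing ``2N - O``
distinct primaries; the first ``N`` form mixture *a*, the last ``N`` form
mixture *b*, so the middle ``O`` positions are the shared block.  The draw is
exchangeable, so this convention is statistically equivalent to any other
placement of the shared components and keeps the shared block addressable in
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InfeasibleDesignError

__all__ = [
    "ModelKind",
    "PrimarySet",
    "MixturePair",
    "MixtureClassSpec",
    "FreshColorPair",
    "draw_primaries",
    "make_mixture_pair",
    "make_class",
    "fresh_random_pair_color",
    "default_overlap_grid",
    "design_to_json",
    "design_from_json",
]

DEFAULT_C = 128
DEFAULT_N_PAIRS = 20


class ModelKind(str, Enum):
    """The three encoding models a stimulus set can be drawn for."""

    MICROBE = "microbe"
    COLOR = "color"
    RING = "ring"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        try:
            return cls(value)
        except ValueError:
            raise ConfigurationError(f"unknown model kind: {value!r}") from None


@dataclass(frozen=True)
class PrimarySet:
    """An ordered pool of ``C`` primary stimuli for one model.

    ``values`` is ``(C,)`` of +-1 scalars for the microbe model, ``(C, 3)``
    RGB vectors of fixed Euclidean norm for the color model, and ``(C,)``
    angles in ``[0, 2*pi)`` for the ring model.
    """

    model_kind: ModelKind
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind.coerce(self.model_kind))
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        if self.model_kind is ModelKind.MICROBE:
            if values.ndim != 1 or not np.all(np.isin(values, (-1, 1))):
                raise ConfigurationError("microbe primaries must be a vector of +-1")
        elif self.model_kind is ModelKind.COLOR:
            if values.ndim != 2 or values.shape[1] != 3:
                raise ConfigurationError("color primaries must be (C, 3) vectors")
        else:
            if values.ndim != 1 or np.any(values < 0) or np.any(values >= 2 * np.pi):
                raise ConfigurationError("ring primaries must be angles in [0, 2*pi)")

    @property
    def C(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MixturePair:
    """Two index sets of size ``N`` over a primary pool, sharing exactly ``O``."""

    components_a: tuple[int, ...]
    components_b: tuple[int, ...]
    N: int
    O: int

    def __post_init__(self) -> None:
        set_a, set_b = set(self.components_a), set(self.components_b)
        if len(set_a) != self.N or len(set_b) != self.N:
            raise ConfigurationError("mixture component sets must have size N")
        if len(set_a & set_b) != self.O:
            raise ConfigurationError("mixture pair overlap does not equal O")

    @property
    def D_pair(self) -> int:
        """Unshared components per mixture, ``N - O``."""
        return self.N - self.O

    @property
    def shared(self) -> frozenset[int]:
        return frozenset(self.components_a) & frozenset(self.components_b)


@dataclass(frozen=True)
class MixtureClassSpec:
    """One (N, O) mixture class and how many pairs to draw for it."""

    N: int
    O: int
    n_pairs: int = DEFAULT_N_PAIRS

    def __post_init__(self) -> None:
        if not (0 <= self.O <= self.N):
            raise ConfigurationError(f"overlap O={self.O} outside [0, N={self.N}]")
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")

    def validate_against(self, C: int) -> None:
        if 2 * self.N - self.O > C:
            raise InfeasibleDesignError(
                f"class (N={self.N}, O={self.O}) needs {2 * self.N - self.O} "
                f"distinct primaries but the pool has only C={C}"
            )


@dataclass(frozen=True)
class FreshColorPair:
    """A color mixture pair with embedded component vectors (no primary pool).

    Models an unbounded-dimensional stimulus space: every pair gets its own
    freshly drawn set of ``2N - O`` normalized component vectors.
    """

    vectors_a: np.ndarray  # (N, 3)
    vectors_b: np.ndarray  # (N, 3)
    N: int
    O: int

    @property
    def D_pair(self) -> int:
        return self.N - self.O


def _color_unit_vectors(n: int, rng: np.random.Generator, norm: float) -> np.ndarray:
    """Coordinate-uniform draws on [0,1]^3 rescaled to the given Euclidean norm.

    Deliberately *not* uniform on the sphere octant: the rescaling of
    cube-uniform coordinates is the stated sampling rule.
    """
    v = rng.uniform(size=(n, 3))
    lengths = np.linalg.norm(v, axis=1, keepdims=True)
    # a coordinate triple of exactly zero length has probability zero
    return v / lengths * norm


def draw_primaries(
    model_kind: ModelKind | str,
    C: int = DEFAULT_C,
    rng: np.random.Generator | None = None,
    *,
    color_norm: float = 1.0 / 30.0,
    seed: int | None = None,
) -> PrimarySet:
    """Draw ``C`` random primary stimuli for the given model.

    microbe: each value +-1 with probability 1/2.
    color:   coordinates uniform on [0, 1], rescaled to norm ``color_norm``.
    ring:    angle uniform on [0, 2*pi).
    """
    model_kind = ModelKind.coerce(model_kind)
    if C < 1:
        raise ConfigurationError("C must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if model_kind is ModelKind.MICROBE:
        values = rng.choice(np.array([-1, 1]), size=C)
    elif model_kind is ModelKind.COLOR:
        values = _color_unit_vectors(C, rng, color_norm)
    else:
        values = rng.uniform(0.0, 2.0 * np.pi, size=C)
    return PrimarySet(model_kind=model_kind, values=values, seed=seed)


def _draw_pair_indices(C: int, N: int, O: int, rng: np.random.Generator) -> np.ndarray:
    if 2 * N - O > C:
        raise InfeasibleDesignError(
            f"cannot draw {2 * N - O} distinct indices from a pool of {C}"
        )
    return rng.choice(C, size=2 * N - O, replace=False)


def make_mixture_pair(
    primaries: PrimarySet, N: int, O: int, rng: np.random.Generator
) -> MixturePair:
    """Draw one pair of N-mixtures from the pool sharing exactly O components."""
    MixtureClassSpec(N=N, O=O, n_pairs=1).validate_against(primaries.C)
    idx = _draw_pair_indices(primaries.C, N, O, rng)
    return MixturePair(
        components_a=tuple(int(i) for i in idx[:N]),
        components_b=tuple(int(i) for i in idx[N - O : 2 * N - O]),
        N=N,
        O=O,
    )


def make_class(
    primaries: PrimarySet, spec: MixtureClassSpec, rng: np.random.Generator
) -> list[MixturePair]:
    """Draw ``spec.n_pairs`` independent mixture pairs for one (N, O) class."""
    spec.validate_against(primaries.C)
    return [make_mixture_pair(primaries, spec.N, spec.O, rng) for _ in range(spec.n_pairs)]


def fresh_random_pair_color(
    N: int,
    O: int,
    rng: np.random.Generator,
    *,
    norm: float | None = None,
) -> FreshColorPair:
    """Color pair whose 2N - O component vectors are drawn fresh, not pooled.

    Component norm defaults to ``1/N`` (equal-part mixing at fixed total
    intensity).
    """
    if not (0 <= O <= N):
        raise ConfigurationError(f"overlap O={O} outside [0, N={N}]")
    if norm is None:
        norm = 1.0 / N
    vectors = _color_unit_vectors(2 * N - O, rng, norm)
    return FreshColorPair(
        vectors_a=vectors[:N], vectors_b=vectors[N - O : 2 * N - O], N=N, O=O
    )


def default_overlap_grid(N: int) -> list[int]:
    """Default overlap grid: coarse steps plus a fine tail near full overlap.

    For N=30 this is [0, 5, 10, 15, 20, 25, 28, 29, 30].
    """
    step = max(1, round(N / 6))
    grid = set(range(0, N + 1, step)) | {max(0, N - 2), max(0, N - 1), N}
    return sorted(grid)


# ---------------------------------------------------------------------------
# JSON round-tripping for reproducibility audits
# ---------------------------------------------------------------------------


def design_to_json(
    primaries: PrimarySet, pairs: Sequence[MixturePair], path=None
) -> str:
    doc = {
        "model_kind": primaries.model_kind.value,
        "seed": primaries.seed,
        "primaries": np.asarray(primaries.values).tolist(),
        "pairs": [
            {
                "components_a": list(p.components_a),
                "components_b": list(p.components_b),
                "N": p.N,
                "O": p.O,
            }
            for p in pairs
        ],
    }
    text = json.dumps(doc, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def design_from_json(source: str) -> tuple[PrimarySet, list[MixturePair]]:
    """Inverse of :func:`design_to_json`; accepts a JSON string or a file path."""
    try:
        doc = json.loads(source)
    except (json.JSONDecodeError, ValueError):
        with open(source) as fh:
            doc = json.load(fh)
    primaries = PrimarySet(
        model_kind=ModelKind(doc["model_kind"]),
        values=np.asarray(doc["primaries"]),
        seed=doc.get("seed"),
    )
    pairs = [
        MixturePair(
            components_a=tuple(p["components_a"]),
            components_b=tuple(p["components_b"]),
            N=p["N"],
            O=p["O"],
        )
        for p in doc["pairs"]
    ]
    return primaries, pairs
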