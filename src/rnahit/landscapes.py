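"""Fitness, similarity, and fidelity landscapes over sequence space.

The replication rate of a polymerase x copying a template y is
``k_rep(x, y) = a * f(x) * s(x, y)`` with fitness f and similarity s
taking values in (0, 1].  Both are "tent" surfaces by default: value 1 on
the high-fidelity manifold R (resp. at spatial distance 0) with
exponential decay ``exp(-k * distance)`` away from it; a linear (affine)
variant interpolates from 1 at distance 0 to a terminus value at
distance n.  The per-site copying fidelity p(x) is the same tent surface
evaluated with its own curvature m, so members of R copy perfectly and
the most distant sequences copy at a configurable floor (0.25 = random
chance under the default m = -log(0.25)/n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .sequences import SequenceSpace, SequenceError, encode, read_fasta


def curvature_from_terminus(terminus: float, n: int) -> float:
    """Curvature k such that the tent surface equals ``terminus`` at
    distance n: k = -log(terminus)/n.  ``terminus`` must lie in (0, 1]."""
    if not 0 < terminus <= 1:
        raise ValueError(f"terminus must be in (0, 1], got {terminus}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return -float(np.log(terminus)) / n


def tent(distance, k: float):
    """Tent surface exp(-k * distance); 1 at distance 0."""
    if k < 0:
        raise ValueError("curvature must be >= 0")
    return np.exp(-k * np.asarray(distance, dtype=float))


def linear(distance, terminus: float, n: int):
    """Affine surface 1 + (terminus - 1)/n * distance; equals terminus at
    distance n."""
    if not 0 < terminus <= 1:
        raise ValueError(f"terminus must be in (0, 1], got {terminus}")
    return 1.0 + (terminus - 1.0) / n * np.asarray(distance, dtype=float)


@dataclass(frozen=True)
class HighFidelitySet:
    """The designated manifold R of maximal-fitness, perfect-fidelity
    sequences: either an explicit member list or a per-position product
    of allowed-base sets."""

    n: int
    codes: np.ndarray  # sorted unique member codes

    def __post_init__(self):
        codes = np.unique(np.asarray(self.codes, dtype=np.int64))
        if codes.size == 0:
            raise SequenceError("high-fidelity set R must be non-empty")
        if codes.min() < 0 or codes.max() >= 4**self.n:
            raise SequenceError("member code out of range for n")
        object.__setattr__(self, "codes", codes)

    @property
    def size(self) -> int:
        return int(self.codes.size)

    def __contains__(self, code: int) -> bool:
        return bool(np.any(self.codes == code))

    @classmethod
    def from_sequences(cls, seqs: list[str]) -> "HighFidelitySet":
        if not seqs:
            raise SequenceError("empty sequence list for R")
        n = len(seqs[0])
        if any(len(s) != n for s in seqs):
            raise SequenceError("members of R must share one length")
        return cls(n, np.array([encode(s) for s in seqs], dtype=np.int64))

    @classmethod
    def from_fasta(cls, path) -> "HighFidelitySet":
        return cls.from_sequences([seq for _, seq in read_fasta(path)])

    @classmethod
    def from_product(cls, allowed: list[list[str]]) -> "HighFidelitySet":
        """R = A_1 x ... x A_n from per-position allowed-base sets."""
        n = len(allowed)
        if n == 0 or any(len(a) == 0 for a in allowed):
            raise SequenceError("product construction needs non-empty A_i")
        codes = np.zeros(1, dtype=np.int64)
        for i, bases in enumerate(allowed):
            digits = np.array([encode(b) for b in bases], dtype=np.int64)
            codes = (codes[:, None] | (digits[None, :] << (2 * i))).ravel()
        return cls(n, codes)

    @classmethod
    def random_product(cls, n: int, q: float, rng: np.random.Generator
                       ) -> "HighFidelitySet":
        """Product-form R where each position is free (|A_i| = 4) with
        probability q and pinned to one random base otherwise; q = 0
        yields a random singleton."""
        if not 0 <= q < 1:
            raise SequenceError("q must be in [0, 1)")
        allowed = []
        for _ in range(n):
            if rng.random() < q:
                allowed.append(list("AUGC"))
            else:
                allowed.append([ "AUGC"[rng.integers(4)] ])
        return cls.from_product(allowed)

    @classmethod
    def random_singleton(cls, n: int, rng: np.random.Generator
                         ) -> "HighFidelitySet":
        return cls(n, np.array([rng.integers(4**n)], dtype=np.int64))


@dataclass
class Landscape:
    """Parameterization of the fitness/similarity/fidelity surfaces.

    For ``form="tent"`` the parameters k, l, m are exponential-decay
    curvatures; for ``form="linear"`` they are terminus values in (0, 1]
    (the surface value at distance n).  ``similarity="constant"`` uses
    the trivial s(x, y) = b instead of the spatial-distance surface.
    """

    form: Literal["tent", "linear"] = "tent"
    k: float = 0.0            # fitness curvature (tent) or terminus (linear)
    l: float = 0.0            # similarity curvature or terminus
    m: float = 0.0            # fidelity curvature or terminus
    similarity: Literal["distance", "constant"] = "distance"
    b: float = 1.0            # constant-similarity level

    def __post_init__(self):
        for name in ("k", "l", "m"):
            v = getattr(self, name)
            if self.form == "tent":
                if not (np.isfinite(v) and v >= 0):
                    raise ValueError(f"{name} must be a finite curvature >= 0")
            else:
                if not 0 < v <= 1:
                    raise ValueError(f"linear terminus {name} must be in (0,1]")
        if not 0 < self.b <= 1:
            raise ValueError("constant similarity b must be in (0, 1]")

    @classmethod
    def tent_from_terminus(cls, n: int, fitness_terminus: float,
                           similarity_terminus: float | None = None,
                           fidelity_terminus: float = 0.25, **kw) -> "Landscape":
        """Tent landscape specified by surface values at distance n (the
        terminus parameterization k = -log(i)/n)."""
        if similarity_terminus is None:
            similarity_terminus = fitness_terminus
        return cls(
            form="tent",
            k=curvature_from_terminus(fitness_terminus, n),
            l=curvature_from_terminus(similarity_terminus, n),
            m=curvature_from_terminus(fidelity_terminus, n),
            **kw,
        )

    # -- pointwise evaluations ------------------------------------------

    def _surface(self, distance, param: float, n: int):
        if self.form == "tent":
            return tent(distance, param)
        return linear(distance, param, n)

    def fitness(self, space: SequenceSpace, R: HighFidelitySet, code):
        """f(x) = surface(H(x, R))."""
        return self._surface(space.manifold_distance(code, R.codes),
                             self.k, space.n)

    def similarity_value(self, space: SequenceSpace, x, y):
        """s(x, y) = surface(S(x, y)) or the constant b."""
        if self.similarity == "constant":
            return self.b if np.ndim(x) == 0 else np.full(np.shape(x), self.b)
        return self._surface(space.spatial_distance(x, y), self.l, space.n)

    def fidelity(self, space: SequenceSpace, R: HighFidelitySet, code):
        """Per-site copying fidelity p(x) = surface(H(x, R)) with its own
        curvature m; equals 1 on R."""
        return self._surface(space.manifold_distance(code, R.codes),
                             self.m, space.n)

    # -- dense tables over the full space -------------------------------

    def fitness_vector(self, space: SequenceSpace, R: HighFidelitySet
                       ) -> np.ndarray:
        return np.asarray(self.fitness(space, R, space.codes()), dtype=float)

    def fidelity_vector(self, space: SequenceSpace, R: HighFidelitySet
                        ) -> np.ndarray:
        return np.asarray(self.fidelity(space, R, space.codes()), dtype=float)

    def similarity_matrix(self, space: SequenceSpace) -> np.ndarray:
        codes = space.codes()
        if self.similarity == "constant":
            return np.full((space.size, space.size), self.b)
        S = space.spatial_distance(codes[:, None], codes[None, :])
        return np.asarray(self._surface(S, self.l, space.n), dtype=float)
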