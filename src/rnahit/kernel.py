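"""Template-directed polymerization as a measure-kernel-function.

A polymerase x copying template y emits the complement of y with per-site
fidelity p(x): each position is copied complement-correctly with
probability p and otherwise mutated to one of the three alternative bases
uniformly.  The number of mutations — the Hamming distance from the
offspring to the template's complement — is Binomial(n, 1 - p), and the
offspring is uniform within each level set H_i(y).  The instantaneous
domain measure nu_t weights ordered (polymerase, template) pairs by their
replication propensity; pushing nu_t through the kernel Q gives the image
measure mu_t = nu_t Q on sequence space, the instantaneous law of the
polymerization output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .sequences import SequenceSpace


class UndefinedMeasureError(ValueError):
    """Raised when the total replication rate is zero and the domain
    measure nu_t is undefined."""


def mutation_count_pmf(p_site: float, n: int) -> np.ndarray:
    """PMF over {0..n} of the number of mutated positions,
    Binomial(n, 1 - p_site); a point mass at 0 when p_site = 1."""
    if not 0 < p_site <= 1:
        raise ValueError(f"per-site fidelity must be in (0, 1], got {p_site}")
    return binom.pmf(np.arange(n + 1), n, 1.0 - p_site)


def kernel_row(space: SequenceSpace, p_site: float, y: int) -> np.ndarray:
    """Dense offspring distribution Q((x, y), .) over E for per-site
    fidelity ``p_site`` and template ``y``.

    Mass ``p^(n-i) * ((1-p)/3)^i`` on each member of the level set
    H_i(y) (distance i from the template complement); rows sum to 1.
    """
    if not 0 < p_site <= 1:
        raise ValueError(f"per-site fidelity must be in (0, 1], got {p_site}")
    n = space.n
    yc = space.complement(int(y))
    d = space.hamming(space.codes(), yc)
    with np.errstate(divide="ignore"):
        row = (p_site ** (n - d)) * (((1.0 - p_site) / 3.0) ** d)
    if p_site == 1.0:  # degenerate: all mass on the template complement
        row = np.zeros(space.size)
        row[yc] = 1.0
    return row


def sample_offspring(space: SequenceSpace, p_site: float, y: int,
                     rng: np.random.Generator) -> int:
    """Draw one offspring of template ``y``: per position, emit the
    complementary base with probability ``p_site``, else one of the three
    other bases uniformly.  Marginal law equals ``kernel_row``."""
    if not 0 < p_site <= 1:
        raise ValueError(f"per-site fidelity must be in (0, 1], got {p_site}")
    n = space.n
    yc = space.complement(int(y))
    if p_site == 1.0:
        return yc
    out = 0
    for i in range(n):
        base = (yc >> (2 * i)) & 3
        if rng.random() >= p_site:
            # uniform over the three alternatives
            base = (base + 1 + rng.integers(3)) & 3
        out |= base << (2 * i)
    return int(out)


@dataclass
class DomainMeasure:
    """nu_t: normalized replication-propensity weights over ordered
    (polymerase, template) pairs of present single strands.

    ``pairs`` holds (x, y) code pairs with nonzero weight; weights sum
    to 1.  ``total_rate`` is the replicative mass k_rep(t) used as the
    normalizer.
    """

    pairs: np.ndarray      # (m, 2) int codes
    weights: np.ndarray    # (m,) probabilities
    total_rate: float

    def weight_of(self, x: int, y: int) -> float:
        hit = (self.pairs[:, 0] == x) & (self.pairs[:, 1] == y)
        return float(self.weights[hit].sum())


def domain_measure(space: SequenceSpace, counts: np.ndarray,
                   fitness: np.ndarray, similarity: np.ndarray,
                   a: float) -> DomainMeasure:
    """Build nu_t from dense single-strand counts.

    Weight of the ordered pair (x, y) is
    ``a f(x) s(x,y) N(x) (N(y) - I(x=y))`` normalized by the total; a
    lone molecule cannot self-pair.  Raises :class:`UndefinedMeasureError`
    when the total replication rate is zero.
    """
    support = np.flatnonzero(counts)
    pairs, w = [], []
    for x in support:
        for y in support:
            mult = counts[x] * (counts[y] - (1 if x == y else 0))
            if mult > 0:
                pairs.append((x, y))
                w.append(a * fitness[x] * similarity[x, y] * mult)
    total = float(np.sum(w)) if w else 0.0
    if total <= 0:
        raise UndefinedMeasureError(
            "total replication rate is zero; nu_t is undefined")
    return DomainMeasure(np.array(pairs, dtype=np.int64),
                         np.asarray(w, dtype=float) / total, total)


def image_measure(space: SequenceSpace, nu: DomainMeasure,
                  fidelity: np.ndarray) -> np.ndarray:
    """mu_t = nu_t Q: dense probability vector over E of the
    instantaneous polymerization output.  ``fidelity`` gives the per-site
    fidelity p(x) for each polymerase code."""
    mu = np.zeros(space.size)
    for (x, y), w in zip(nu.pairs, nu.weights):
        mu += w * kernel_row(space, float(fidelity[x]), int(y))
    return mu


def aggregate_on_partition(mu: np.ndarray, class_of: np.ndarray,
                           n_classes: int) -> np.ndarray:
    """Aggregate a measure over E onto partition classes (e.g. the
    manifold level sets H_i); returns a vector of class masses."""
    return np.bincount(class_of, weights=mu, minlength=n_classes)
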