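import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, chisquare

from rnahit import (
    DomainMeasure, HighFidelitySet, Landscape, SequenceSpace,
    UndefinedMeasureError, aggregate_on_partition, domain_measure,
    image_measure, kernel_row, mutation_count_pmf, sample_offspring,
)
from rnahit.sequences import hamming
from rnahit.ssa import PopulationState


@given(st.floats(0.01, 1.0), st.integers(1, 6))
def test_mutation_count_pmf_is_binomial(p, n):
    pmf = mutation_count_pmf(p, n)
    assert pmf.sum() == pytest.approx(1.0)
    assert np.allclose(pmf, binom.pmf(np.arange(n + 1), n, 1 - p))


@given(st.floats(0.05, 0.999), st.integers(0, 63))
@settings(max_examples=40)
def test_kernel_row_sums_to_one(p, y):
    space = SequenceSpace(3)
    row = kernel_row(space, p, y)
    assert row.sum() == pytest.approx(1.0)
    assert (row > 0).all()


def test_kernel_row_matches_bruteforce_enumeration():
    """Per-offspring mass equals the product over positions of the
    per-site emission probabilities (independent brute force)."""
    space = SequenceSpace(2)
    p = 0.8
    for y in range(16):
        yc = space.complement(y)
        row = kernel_row(space, p, y)
        for z in range(16):
            prob = 1.0
            for i in range(2):
                want = (yc >> (2 * i)) & 3
                got = (z >> (2 * i)) & 3
                prob *= p if got == want else (1 - p) / 3
            assert row[z] == pytest.approx(prob)


def test_level_set_mass_is_binomial():
    space = SequenceSpace(3)
    p = 0.7
    y = 37
    row = kernel_row(space, p, y)
    part = space.level_sets(y)  # classes by distance to yc
    mass = aggregate_on_partition(row, part.class_of, 4)
    assert np.allclose(mass, mutation_count_pmf(p, 3))
    # class sizes C(n,i) 3^i
    assert list(part.sizes()) == [math.comb(3, i) * 3**i for i in range(4)]


def test_kernel_row_perfect_fidelity_point_mass():
    space = SequenceSpace(3)
    y = 12
    row = kernel_row(space, 1.0, y)
    assert row[space.complement(y)] == 1.0
    assert row.sum() == 1.0


def test_sample_offspring_matches_kernel_row():
    space = SequenceSpace(2)
    p, y = 0.6, 9
    row = kernel_row(space, p, y)
    rng = np.random.default_rng(123)
    draws = np.array([sample_offspring(space, p, y, rng)
                      for _ in range(20000)])
    observed = np.bincount(draws, minlength=16)
    stat, pval = chisquare(observed, row * draws.size)
    assert pval > 1e-4


def test_sample_offspring_perfect_fidelity():
    space = SequenceSpace(3)
    rng = np.random.default_rng(0)
    for y in (0, 17, 63):
        assert sample_offspring(space, 1.0, y, rng) == space.complement(y)


def _toy_measure(space, counts, a=2.0, terminus=0.05):
    rng = np.random.default_rng(7)
    R = HighFidelitySet.random_singleton(space.n, rng)
    ls = Landscape.tent_from_terminus(space.n, terminus)
    f = ls.fitness_vector(space, R)
    S = ls.similarity_matrix(space)
    return R, ls, f, S, domain_measure(space, counts, f, S, a)


def test_domain_measure_weights():
    space = SequenceSpace(2)
    counts = np.zeros(16, dtype=int)
    counts[[3, 5]] = [2, 1]
    R, ls, f, S, nu = _toy_measure(space, counts)
    assert nu.weights.sum() == pytest.approx(1.0)
    # hand total: ordered pairs (3,3)x2, (3,5), (5,3)
    expect = (2.0 * f[3] * S[3, 3] * 2 * 1
              + 2.0 * f[3] * S[3, 5] * 2 * 1
              + 2.0 * f[5] * S[5, 3] * 1 * 2)
    assert nu.total_rate == pytest.approx(expect)
    # lone-molecule self pair excluded
    assert nu.weight_of(5, 5) == 0.0
    assert nu.weight_of(3, 3) > 0.0


def test_domain_measure_undefined_for_lone_molecule():
    space = SequenceSpace(2)
    counts = np.zeros(16, dtype=int)
    counts[4] = 1
    with pytest.raises(UndefinedMeasureError):
        _toy_measure(space, counts)


def test_image_measure_equals_dense_product():
    """mu = nu Q computed by the module equals an explicit dense
    matrix-vector product over all ordered pairs."""
    space = SequenceSpace(2)
    counts = np.zeros(16, dtype=int)
    counts[[1, 6, 11]] = [1, 2, 1]
    R, ls, f, S, nu = _toy_measure(space, counts)
    p = ls.fidelity_vector(space, R)
    mu = image_measure(space, nu, p)
    dense = np.zeros(16)
    for (x, y), w in zip(nu.pairs, nu.weights):
        dense += w * kernel_row(space, float(p[x]), int(y))
    # independent route: accumulate via explicit per-z loop
    check = np.zeros(16)
    for (x, y), w in zip(nu.pairs, nu.weights):
        yc = space.complement(int(y))
        for z in range(16):
            d = hamming(yc, z, 2)
            check[z] += w * (p[x] ** (2 - d)) * (((1 - p[x]) / 3.0) ** d)
    assert mu.sum() == pytest.approx(1.0)
    assert np.allclose(mu, dense)
    assert np.allclose(mu, check)


def test_aggregate_preserves_mass():
    space = SequenceSpace(3)
    rng = np.random.default_rng(3)
    mu = rng.random(64)
    part = space.level_sets(np.array([5]))
    agg = aggregate_on_partition(mu, part.class_of, 4)
    assert agg.sum() == pytest.approx(mu.sum())


def test_invalid_fidelity_rejected():
    space = SequenceSpace(2)
    with pytest.raises(ValueError):
        kernel_row(space, 0.0, 1)
    with pytest.raises(ValueError):
        mutation_count_pmf(1.2, 3)
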