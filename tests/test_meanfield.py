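import numpy as np
import pytest

from rnahit import (
    HighFidelitySet, Landscape, MeanFieldODE, RateConstants, SequenceSpace,
    fixed_point_report,
)
from rnahit.ssa import CHANNELS, PopulationState, channel_rates
from rnahit.kernel import kernel_row


def _system(n=2, seed=0, terminus=0.01, **rates_kw):
    rng = np.random.default_rng(seed)
    space = SequenceSpace(n)
    R = HighFidelitySet.random_singleton(n, rng)
    ls = Landscape.tent_from_terminus(n, terminus)
    ode = MeanFieldODE(space, ls, R, RateConstants(a=10.0, **rates_kw))
    return space, R, ls, ode


def test_pure_high_fidelity_state_is_equilibrium():
    for seed in range(3):
        space, R, ls, ode = _system(seed=seed)
        v = ode.pure_state(int(R.codes[0]), 1.0)
        assert ode.residual(v) < 1e-12


def test_two_molecules_are_not_an_equilibrium():
    """A lone molecule of any sequence is inert (replication needs an
    ordered pair), but two molecules replicate: the state stops being a
    fixed point."""
    space, R, ls, ode = _system(seed=0)
    other = (int(R.codes[0]) + 1) % space.size
    assert ode.residual(ode.pure_state(other, 1.0)) < 1e-12
    assert ode.residual(ode.pure_state(other, 2.0)) > 1e-6
    assert ode.residual(ode.pure_state(int(R.codes[0]), 2.0)) > 1e-6


def test_equilibrium_is_unstable_without_zero_eigenvalue():
    space, R, ls, ode = _system(seed=1)
    v = ode.pure_state(int(R.codes[0]), 1.0)
    stab = ode.stability(v)
    assert not stab["has_zero_eigenvalue"]
    assert stab["n_positive"] >= 1
    assert stab["classification"] == "unstable"


def test_jacobian_matches_finite_differences():
    space, R, ls, ode = _system(seed=2, k_decay=0.2)
    rng = np.random.default_rng(3)
    v = rng.random(ode.dim)
    J = ode.jacobian(v)
    eps = 1e-6
    for j in rng.integers(0, ode.dim, size=10):
        e = np.zeros(ode.dim)
        e[j] = eps
        col = (ode.rhs(v + e) - ode.rhs(v - e)) / (2 * eps)
        assert np.allclose(J[:, j], col, atol=1e-5), j


def test_rhs_equals_expected_ssa_drift():
    """Dual route: at an integer state, the ODE vector field equals the
    expected instantaneous change of the counts computed directly from
    the channel propensities and the offspring kernel."""
    space, R, ls, ode = _system(seed=4)
    rng = np.random.default_rng(5)
    state = PopulationState(space)
    for c in rng.integers(0, space.size, size=12):
        state.Ns[c] += 1
    for _ in range(2):
        c = int(rng.integers(space.size))
        state.Nd[min(c, int(space.complement(c)))] += 1

    f = ls.fitness_vector(space, R)
    p = ls.fidelity_vector(space, R)
    S = ls.similarity_matrix(space)
    drift_s = np.zeros(space.size)
    drift_d = np.zeros(space.size)
    Ns = state.Ns.astype(float)
    perm = space.complement_perm
    # duplex formation consumes x and xc, produces the canonical duplex
    pair = ode.rates.kds * Ns * Ns[perm]
    drift_s -= pair
    can = space.codes() < perm
    drift_d[can] += pair[can]
    # dissociation
    Nd = state.Nd.astype(float)
    drift_d -= ode.rates.kss * Nd
    drift_s += ode.rates.kss * (Nd + Nd[perm])
    # replication: each ordered pair (x, y) adds kernel_row(p(x), y)
    for x in np.flatnonzero(state.Ns):
        for y in np.flatnonzero(state.Ns):
            mult = Ns[x] * (Ns[y] - (1 if x == y else 0))
            if mult <= 0:
                continue
            rate = ode.rates.a * f[x] * S[x, y] * mult
            drift_s += rate * kernel_row(space, float(p[x]), int(y))

    v = np.concatenate([Ns, Nd[space.codes()[can]]])
    rhs = ode.rhs(v)
    assert np.allclose(rhs[:space.size], drift_s, atol=1e-9)
    dd = np.zeros(space.size)
    dd[can] = rhs[space.size:]
    assert np.allclose(dd[can], drift_d[can], atol=1e-9)


def test_newton_finds_equilibrium_from_perturbation():
    space, R, ls, ode = _system(seed=6)
    rng = np.random.default_rng(7)
    start = ode.pure_state(int(R.codes[0]), 1.0) + 1e-3 * rng.random(ode.dim)
    fp = ode.find_fixed_point(start)
    assert ode.residual(fp) < 1e-12
    assert fp[int(R.codes[0])] == pytest.approx(1.0, abs=1e-8)


def test_integration_grows_from_perturbed_equilibrium():
    """Instability is dynamical: a small perturbation grows under the
    flow."""
    space, R, ls, ode = _system(seed=8)
    x = int(R.codes[0])
    v0 = ode.pure_state(x, 1.0)
    v0[x] += 0.05  # a second (partial) molecule
    # horizon well before the finite-time blow-up of the quadratic
    # autocatalysis (~0.3 for this perturbation size)
    sol = ode.integrate(v0, (0.0, 0.2))
    assert sol.success
    # strand mass (singles + 2 per duplex) can only grow under
    # replication; duplex chemistry conserves it
    mass0 = v0[:space.size].sum() + 2 * v0[space.size:].sum()
    mass1 = sol.y[:space.size, -1].sum() + 2 * sol.y[space.size:, -1].sum()
    assert mass1 > mass0 + 0.1


def test_report_contract():
    rep = fixed_point_report(n=2, seed=0)
    assert rep["residual"] < 1e-12
    assert rep["high_fidelity_concentration"] == pytest.approx(1.0, abs=1e-8)
    assert rep["n_positive_eigenvalues"] >= 1
    assert not rep["has_zero_eigenvalue"]
    assert rep["classification"] == "unstable"


def test_dimension_guard():
    from rnahit.sequences import SequenceError
    rng = np.random.default_rng(0)
    space = SequenceSpace(4)
    R = HighFidelitySet.random_singleton(4, rng)
    ls = Landscape.tent_from_terminus(4, 0.01)
    with pytest.raises(SequenceError):
        MeanFieldODE(space, ls, R, RateConstants())
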