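import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rnahit import (
    CHANNELS, HighFidelitySet, Landscape, RateConstants, SequenceSpace,
    channel_rates, channel_rates_naive, simulate,
)
from rnahit.ssa import PopulationState, _choice


def _random_state(space, rng, n_singles=20, n_dups=4):
    st_ = PopulationState(space)
    for c in rng.integers(0, space.size, size=n_singles):
        st_.Ns[c] += 1
    for _ in range(n_dups):
        c = int(rng.integers(space.size))
        st_.Nd[min(c, int(space.complement(c)))] += 1
    return st_


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_channel_rates_match_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    space = SequenceSpace(2)
    R = HighFidelitySet.random_singleton(2, rng)
    ls = Landscape.tent_from_terminus(2, 0.05)
    f = ls.fitness_vector(space, R)
    S = ls.similarity_matrix(space)
    rates = RateConstants(a=float(rng.uniform(0.1, 5)),
                          k_decay=float(rng.uniform(0, 1)),
                          k_clay_o=float(rng.uniform(0, 1)),
                          k_clay_p=float(rng.uniform(0, 1)),
                          k_mic=float(rng.uniform(0, 1)))
    state = _random_state(space, rng, n_singles=int(rng.integers(1, 30)),
                          n_dups=int(rng.integers(0, 5)))
    fast = channel_rates(state, rates, f, S)
    slow = channel_rates_naive(state, rates, f, S)
    for ch in CHANNELS + ("total",):
        assert fast[ch] == pytest.approx(slow[ch], rel=1e-10, abs=1e-12)


def test_replication_rate_zero_for_lone_molecule(space3, setup3):
    state = PopulationState.from_codes(space3, [7])
    f = setup3["landscape"].fitness_vector(space3, setup3["R"])
    S = setup3["landscape"].similarity_matrix(space3)
    ch = channel_rates(state, RateConstants(a=10.0), f, S)
    assert ch["rna_poly"] == 0.0


def test_choice_is_proportional():
    rng = np.random.default_rng(11)
    w = np.array([0.0, 2.0, 0.0, 1.0, 3.0])
    draws = np.bincount([_choice(rng, w) for _ in range(60_000)], minlength=5)
    assert draws[0] == 0 and draws[2] == 0
    freq = draws / draws.sum()
    assert np.allclose(freq[[1, 3, 4]], np.array([2, 1, 3]) / 6, atol=0.01)


def test_interevent_time_is_exponential_with_total_rate(setup3):
    """Frozen initial state: the first SSA waiting time across many seeds
    follows Exp(total rate)."""
    s = setup3
    f = s["landscape"].fitness_vector(s["space"], s["R"])
    S = s["landscape"].similarity_matrix(s["space"])
    state = PopulationState.from_codes(s["space"], s["init"])
    total = channel_rates(state, s["rates"], f, S)["total"]
    waits = []
    for seed in range(3000):
        traj = simulate(s["space"], s["landscape"], s["R"], s["rates"],
                        s["init"], budget=1, rng=np.random.default_rng(seed),
                        stop_on=None)
        waits.append(traj.times[1])
    ks = stats.kstest(waits, "expon", args=(0, 1.0 / total))
    assert ks.pvalue > 1e-3


def test_channel_frequencies_match_rate_ratios(setup3):
    """Channel selection over 1e5 draws agrees with propensity ratios
    within 3 sigma."""
    s = setup3
    rates = RateConstants(a=s["rates"].a, k_decay=0.5, k_clay_o=0.4,
                          k_clay_p=0.3, k_mic=0.2)
    f = s["landscape"].fitness_vector(s["space"], s["R"])
    S = s["landscape"].similarity_matrix(s["space"])
    state = PopulationState.from_codes(s["space"], s["init"])
    ch = channel_rates(state, rates, f, S)
    w = np.array([ch[c] for c in CHANNELS])
    p = w / w.sum()
    rng = np.random.default_rng(99)
    N = 100_000
    counts = np.bincount([_choice(rng, w) for _ in range(N)],
                         minlength=len(CHANNELS))
    for i, c in enumerate(CHANNELS):
        if p[i] == 0:
            assert counts[i] == 0
            continue
        sigma = np.sqrt(N * p[i] * (1 - p[i]))
        assert abs(counts[i] - N * p[i]) <= 3 * sigma, c


def test_simulate_is_deterministic_per_seed(setup3):
    s = setup3
    kw = dict(budget=300, stop_on=None, record_events=True)
    traj_a = simulate(s["space"], s["landscape"], s["R"], s["rates"], s["init"],
                  rng=np.random.default_rng(5), **kw)
    traj_b = simulate(s["space"], s["landscape"], s["R"], s["rates"], s["init"],
                  rng=np.random.default_rng(5), **kw)
    assert np.array_equal(traj_a.times, traj_b.times)
    assert np.array_equal(traj_a.K, traj_b.K)
    assert [(e.channel, e.reactants, e.products) for e in traj_a.events] == \
        [(e.channel, e.reactants, e.products) for e in traj_b.events]


def test_event_bookkeeping_conserves_counts(setup3):
    """Replaying the event log from the initial state reproduces the
    final dense count vectors."""
    s = setup3
    traj = simulate(s["space"], s["landscape"], s["R"], s["rates"],
                    s["init"], budget=400,
                    rng=np.random.default_rng(21), stop_on=None,
                    record_events=True)
    state = PopulationState.from_codes(s["space"], s["init"])
    consuming = {"ds_form", "ds_dissoc", "decay"}
    for ev in traj.events:
        if ev.channel in consuming:  # polymerization is catalytic
            for kind, code in ev.reactants:
                (state.Ns if kind == "ss" else state.Nd)[code] -= 1
        for kind, code in ev.products:
            (state.Ns if kind == "ss" else state.Nd)[code] += 1
        state.check()
    assert np.array_equal(state.Ns, traj.final_state.Ns)
    assert np.array_equal(state.Nd, traj.final_state.Nd)
    assert state.K == traj.K[-1]


def test_trajectory_series_shapes(setup3):
    s = setup3
    traj = simulate(s["space"], s["landscape"], s["R"], s["rates"],
                    s["init"], budget=100, rng=np.random.default_rng(2),
                    stop_on=None, measure_every=25)
    assert len(traj.times) == len(traj.K) == len(traj.V) == traj.n_reactions + 1
    assert traj.times[0] == 0.0
    assert (np.diff(traj.times) > 0).all()
    assert traj.K[0] == len(s["init"])
    # measures recorded at 0, 25, 50, 75, 100 with one row per class
    assert len(traj.measures) == 5 * (s["space"].n + 1)
    conc = traj.measures.groupby("reaction_index")["concentration"].sum()
    assert np.allclose(conc, 1.0)


def test_pure_birth_process_count_law():
    """With only the zero-order clay channel active, the reaction count
    by time t is Poisson(rate*t): check mean/variance of event times via
    the exact Gamma law of the k-th arrival."""
    space = SequenceSpace(2)
    rng = np.random.default_rng(1)
    R = HighFidelitySet.random_singleton(2, rng)
    ls = Landscape.tent_from_terminus(2, 0.05)
    rate = 3.0
    rates = RateConstants(kds=0.0, kss=0.0, a=0.0, k_clay_o=rate)
    k = 40
    arrivals = []
    for seed in range(400):
        traj = simulate(space, ls, R, rates, [0], budget=k,
                        rng=np.random.default_rng(seed), stop_on=None)
        arrivals.append(traj.end_time)
    ks = stats.kstest(arrivals, "gamma", args=(k, 0, 1.0 / rate))
    assert ks.pvalue > 1e-3


def test_rate_constants_validation():
    with pytest.raises(ValueError):
        RateConstants(kds=-1.0)
    with pytest.raises(ValueError):
        RateConstants(p_clay=0.0)
    with pytest.raises(ValueError):
        RateConstants(p_clay=1.5)


def test_budget_zero_returns_initial_state(setup3):
    s = setup3
    traj = simulate(s["space"], s["landscape"], s["R"], s["rates"],
                    s["init"], budget=0, rng=np.random.default_rng(0),
                    stop_on=None)
    assert traj.n_reactions == 0
    assert traj.end_time == 0.0
    assert traj.hitting["tau_v"].censored
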