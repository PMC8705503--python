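"""Exact stochastic simulation of the replicating RNA reaction network.

Reaction channels (propensities are functionals of the counting measure
N_t over single strands and duplexes):

======================  ======================================  ======
channel                 propensity                              dK
======================  ======================================  ======
``ds_form``             (1/2) sum_x kds N({x}) N({xc})          -1
``ds_dissoc``           kss * (number of duplex molecules)      +1
``rna_poly``            sum_{x,y} a f(x) s(x,y) N(x)(N(y)-1xy)  +1
``decay``               k_decay * (single-strand molecules)     -1
``clay_oligo``          k_clay_o (zero order)                   +1
``clay_poly``           k_clay_p * (single-strand molecules)    +1
``vesiculate``          k_mic * (single-strand molecules)        0
======================  ======================================  ======

Inter-event times are exponential with the grand total rate; channels and
reactants are chosen proportionally to their propensity contributions
(Gillespie's direct method).  Decay acts on single strands only (duplexes
are taken as stable).  Species counts live in dense vectors over the full
4^n space, so channel totals are exact dense-linear-algebra recomputes
each step; a naive dictionary-based recompute is provided as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .sequences import SequenceSpace
from .landscapes import Landscape, HighFidelitySet
from .kernel import sample_offspring
from .hitting import HittingMonitor

CHANNELS = ("ds_form", "ds_dissoc", "rna_poly", "decay",
            "clay_oligo", "clay_poly", "vesiculate")


@dataclass
class RateConstants:
    """Rate constants of the reaction network (all >= 0)."""

    kds: float = 1.0        # duplex formation
    kss: float = 1.0        # duplex dissociation
    a: float = 10.0         # replication scale in k_rep = a f s
    k_decay: float = 0.0    # single-strand decay
    k_clay_o: float = 0.0   # clay oligomerization (zero order)
    k_clay_p: float = 0.0   # clay polymerization (per single strand)
    p_clay: float = 0.9     # clay per-site copying fidelity
    k_mic: float = 0.0      # vesiculation (per single strand)

    def __post_init__(self):
        for name in ("kds", "kss", "a", "k_decay", "k_clay_o",
                     "k_clay_p", "k_mic"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if not 0 < self.p_clay <= 1:
            raise ValueError("clay fidelity p_clay must be in (0, 1]")


@dataclass
class EventRecord:
    """One logged reaction event."""

    index: int
    time: float
    channel: str
    reactants: tuple
    products: tuple


class PopulationState:
    """Multiset of single strands and duplexes as dense count vectors.

    ``Ns[x]`` counts single-strand molecules of sequence x; ``Nd[c]``
    counts duplex molecules under the canonical key c = min(x, xc).
    """

    def __init__(self, space: SequenceSpace):
        self.space = space
        self.Ns = np.zeros(space.size, dtype=np.int64)
        self.Nd = np.zeros(space.size, dtype=np.int64)

    @classmethod
    def from_codes(cls, space: SequenceSpace, codes) -> "PopulationState":
        st = cls(space)
        for c in codes:
            st.Ns[int(c)] += 1
        return st

    def copy(self) -> "PopulationState":
        st = PopulationState(self.space)
        st.Ns = self.Ns.copy()
        st.Nd = self.Nd.copy()
        return st

    def canonical(self, code: int) -> int:
        return min(int(code), int(self.space.complement(code)))

    @property
    def K(self) -> int:
        """Total molecule count N_t(G)."""
        return int(self.Ns.sum() + self.Nd.sum())

    @property
    def n_singles(self) -> int:
        return int(self.Ns.sum())

    def strand_count(self) -> int:
        """Total strands: singles + 2 per duplex (conserved by ds events)."""
        return int(self.Ns.sum() + 2 * self.Nd.sum())

    def check(self) -> None:
        if (self.Ns < 0).any() or (self.Nd < 0).any():
            raise RuntimeError("negative species count: bookkeeping bug")

    def to_fasta_records(self):
        from .sequences import decode
        recs = []
        for x in np.flatnonzero(self.Ns):
            recs.append((f"ss_{decode(int(x), self.space.n)}|count={self.Ns[x]}",
                         decode(int(x), self.space.n)))
        for c in np.flatnonzero(self.Nd):
            recs.append((f"ds_{decode(int(c), self.space.n)}|count={self.Nd[c]}",
                         decode(int(c), self.space.n)))
        return recs


def channel_rates(state: PopulationState, rates: RateConstants,
                  fitness: np.ndarray, similarity: np.ndarray) -> dict:
    """Per-channel propensity totals and the grand total (dense path)."""
    state.check()
    Ns = state.Ns.astype(float)
    perm = state.space.complement_perm
    out = {
        "ds_form": 0.5 * rates.kds * float(Ns @ Ns[perm]),
        "ds_dissoc": rates.kss * float(state.Nd.sum()),
        "decay": rates.k_decay * float(Ns.sum()),
        "clay_oligo": rates.k_clay_o,
        "clay_poly": rates.k_clay_p * float(Ns.sum()),
        "vesiculate": rates.k_mic * float(Ns.sum()),
    }
    SN = similarity @ Ns
    rows = fitness * Ns * (SN - np.diag(similarity))
    out["rna_poly"] = rates.a * float(rows.sum())
    out["total"] = float(sum(out[c] for c in CHANNELS))
    return out


def channel_rates_naive(state: PopulationState, rates: RateConstants,
                        fitness: np.ndarray, similarity: np.ndarray) -> dict:
    """Oracle: loop over the full species space exactly as the rate sums
    are written, with no vectorization or support restriction."""
    sp = state.space
    ds = sum(rates.kds * state.Ns[x] * state.Ns[sp.complement(x)]
             for x in range(sp.size)) / 2.0
    ss = rates.kss * sum(int(state.Nd[c]) for c in range(sp.size))
    rep = 0.0
    for x in range(sp.size):
        for y in range(sp.size):
            mult = state.Ns[x] * (state.Ns[y] - (1 if x == y else 0))
            rep += rates.a * fitness[x] * similarity[x, y] * mult
    out = {
        "ds_form": float(ds), "ds_dissoc": float(ss), "rna_poly": float(rep),
        "decay": rates.k_decay * float(state.Ns.sum()),
        "clay_oligo": rates.k_clay_o,
        "clay_poly": rates.k_clay_p * float(state.Ns.sum()),
        "vesiculate": rates.k_mic * float(state.Ns.sum()),
    }
    out["total"] = float(sum(out[c] for c in CHANNELS))
    return out


@dataclass
class Trajectory:
    """Result of one SSA run: time series, optional event log, optional
    measure snapshots, and online hitting records."""

    n: int
    I: int
    budget: int
    seed: Optional[int]
    times: np.ndarray
    K: np.ndarray
    V: np.ndarray
    n_reactions: int
    end_time: float
    stopped_on: Optional[str]
    events: Optional[list] = None
    measures: Optional[pd.DataFrame] = None
    hitting: dict = field(default_factory=dict)
    final_state: Optional[PopulationState] = None
    rep_mass: Optional[np.ndarray] = None
    rep_mass_unrestricted: Optional[np.ndarray] = None


def _choice(rng: np.random.Generator, weights: np.ndarray) -> int:
    """Sample an index proportional to non-negative weights."""
    c = np.cumsum(weights)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def simulate(space: SequenceSpace, landscape: Landscape, R: HighFidelitySet,
             rates: RateConstants, init_codes, budget: int,
             rng: np.random.Generator | int,
             stop_on: Optional[str] = "tau_v", v: float = 0.25,
             record_events: bool = False, measure_every: int = 0,
             tau_min_mode: str = "last") -> Trajectory:
    """Run one exact SSA trajectory of the (non-spatial) network.

    Parameters
    ----------
    init_codes : sequence of int
        Initial single-strand molecules (I = len(init_codes)).
    budget : int
        Maximum number of reactions N; the run is censored there.
    stop_on : str or None
        Hitting event at which to stop early ("tau_v" by default, the
        volume-fraction hit), or None to always exhaust the budget.
    v : float
        Volume-fraction threshold for tau_v.
    measure_every : int
        If > 0, record concentration/growth/mu_t snapshots on the
        manifold partition every that many reactions.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    if budget < 0:
        raise ValueError("reaction budget must be >= 0")

    state = PopulationState.from_codes(space, init_codes)
    I = state.K
    fitness = landscape.fitness_vector(space, R)
    fidelity = landscape.fidelity_vector(space, R)
    similarity = landscape.similarity_matrix(space)
    s_diag = np.diag(similarity).copy()
    perm = space.complement_perm
    canonical_mask = space.codes() < perm
    partition = space.level_sets(R.codes)
    in_R = np.zeros(space.size, dtype=bool)
    in_R[R.codes] = True
    # duplex canonical keys whose pair contains a member of R
    dup_R = np.zeros(space.size, dtype=bool)
    dup_R[np.minimum(R.codes, perm[R.codes])] = True

    monitor = HittingMonitor(I=I, v=v, tau_min_mode=tau_min_mode)

    def volume_fraction(K: int) -> float:
        if K <= 0:
            return 0.0
        return float(state.Ns[in_R].sum() + state.Nd[dup_R].sum()) / K

    t = 0.0
    K = state.K
    times, Ks, Vs = [0.0], [K], [volume_fraction(K)]
    events: list = [] if record_events else None
    measures: list = [] if measure_every else None
    monitor.observe(0.0, K, Vs[0])

    def snapshot(idx: int):
        cls_s = partition.class_of
        # a duplex is one molecule; both its strands share a class
        counts = np.bincount(cls_s, weights=state.Ns, minlength=space.n + 1)
        counts += np.bincount(cls_s, weights=state.Nd, minlength=space.n + 1)
        mu_cls = _mu_on_partition(space, state, fitness, fidelity,
                                  similarity, s_diag, partition)
        for i in range(space.n + 1):
            measures.append({
                "time": t, "reaction_index": idx, "class": i,
                "count": counts[i],
                "concentration": counts[i] / max(state.K, 1),
                "mu_mass": mu_cls[i],
            })

    if measure_every:
        snapshot(0)

    stopped_on = None
    n_done = 0
    for step in range(budget):
        ch = channel_rates(state, rates, fitness, similarity)
        total = ch["total"]
        if total <= 0:
            stopped_on = "absorbing"
            break
        t += rng.exponential(1.0 / total)
        c_idx = _choice(rng, np.array([ch[c] for c in CHANNELS]))
        channel = CHANNELS[c_idx]
        reactants, products = (), ()

        if channel == "ds_form":
            w = (state.Ns * state.Ns[perm]).astype(float)
            w[~canonical_mask] = 0.0
            x = _choice(rng, w)
            xc = int(perm[x])
            state.Ns[x] -= 1
            state.Ns[xc] -= 1
            state.Nd[x] += 1
            K -= 1
            reactants, products = (("ss", x), ("ss", xc)), (("ds", x),)
        elif channel == "ds_dissoc":
            d = _choice(rng, state.Nd.astype(float))
            state.Nd[d] -= 1
            state.Ns[d] += 1
            state.Ns[int(perm[d])] += 1
            K += 1
            reactants, products = (("ds", d),), (("ss", d), ("ss", int(perm[d])))
        elif channel == "rna_poly":
            Nsf = state.Ns.astype(float)
            rows = fitness * Nsf * ((similarity @ Nsf) - s_diag)
            x = _choice(rng, rows)
            wy = similarity[x] * Nsf
            wy[x] -= s_diag[x]
            y = _choice(rng, wy)
            z = sample_offspring(space, float(fidelity[x]), y, rng)
            state.Ns[z] += 1
            K += 1
            reactants, products = (("ss", x), ("ss", y)), (("ss", z),)
        elif channel == "decay":
            x = _choice(rng, state.Ns.astype(float))
            state.Ns[x] -= 1
            K -= 1
            reactants, products = (("ss", x),), ()
        elif channel == "clay_oligo":
            z = int(rng.integers(space.size))
            state.Ns[z] += 1
            K += 1
            reactants, products = (), (("ss", z),)
        elif channel == "clay_poly":
            x = _choice(rng, state.Ns.astype(float))
            z = sample_offspring(space, rates.p_clay, x, rng)
            state.Ns[z] += 1
            K += 1
            reactants, products = (("ss", x),), (("ss", z),)
        else:  # vesiculate has no effect in the well-mixed engine
            reactants, products = (), ()

        n_done = step + 1
        Vt = volume_fraction(K)
        times.append(t)
        Ks.append(K)
        Vs.append(Vt)
        if record_events:
            events.append(EventRecord(n_done, t, channel, reactants, products))
        if measure_every and n_done % measure_every == 0:
            snapshot(n_done)
        monitor.observe(t, K, Vt)
        if stop_on is not None and monitor.fired(stop_on):
            stopped_on = stop_on
            break

    return Trajectory(
        n=space.n, I=I, budget=budget, seed=seed,
        times=np.asarray(times), K=np.asarray(Ks, dtype=np.int64),
        V=np.asarray(Vs), n_reactions=n_done, end_time=t,
        stopped_on=stopped_on, events=events,
        measures=pd.DataFrame(measures) if measure_every else None,
        hitting=monitor.records(censor_time=t),
        final_state=state,
    )


def _mu_on_partition(space, state, fitness, fidelity, similarity,
                     s_diag, partition) -> np.ndarray:
    """mu_t aggregated on the manifold partition, grouping polymerases by
    their (few) distinct fidelity values for speed.  Returns zeros when
    the replicative mass is zero (nu_t undefined)."""
    Ns = state.Ns.astype(float)
    SN = similarity @ Ns
    rows = fitness * Ns * (SN - s_diag)
    total = rows.sum()
    n_cls = space.n + 1
    if total <= 0:
        return np.zeros(n_cls)
    # W[x, y] = f(x) s(x,y) N(x)(N(y) - 1{x=y}) / total; the offspring law
    # of (x, y) depends on x only through p(x)
    mu = np.zeros(space.size)
    D = space.hamming_table
    support = np.flatnonzero(Ns)
    for p in np.unique(fidelity[support]):
        xs = support[fidelity[support] == p]
        wy = np.zeros(space.size)  # template weights under this fidelity
        for x in xs:
            wyx = similarity[x] * Ns
            wyx[x] -= s_diag[x]
            wy += fitness[x] * Ns[x] * wyx
        if p == 1.0:
            coef = np.zeros(space.n + 1)
            coef[0] = 1.0
        else:
            d = np.arange(space.n + 1)
            coef = (p ** (space.n - d)) * (((1 - p) / 3.0) ** d)
        # mu[z] += sum_y wy[y] coef[h(yc, z)]
        yc = space.complement_perm
        mu += (wy[:, None] * coef[D[yc]]).sum(axis=0)
    mu /= total
    return np.bincount(partition.class_of, weights=mu, minlength=n_cls)
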