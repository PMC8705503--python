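"""Spatially marked SSA with vesicle compartments.

Each molecule carries a position on the 1-D projected domain [-T, T].
Vesiculation events create intervals (vesicles) centered on a randomly
chosen single strand; intervals may nest but never cross, and a proposed
vesicle that would cross an existing one is rejected.  Replication pairs
are restricted to molecules sharing the same *innermost* vesicle region,
so the total replicative mass is always <= the unrestricted (well-mixed)
value and strictly smaller as soon as two molecules are separated by a
vesicle boundary — the trade-off between compartmentalization and
replicative mass.

Only replication is spatially restricted; duplex chemistry, decay, and
clay channels remain well-mixed.  Populations here are molecule lists,
so this engine is meant for modest K; the dense count engine in
:mod:`rnahit.ssa` is the workhorse for sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import SequenceSpace
from .landscapes import Landscape, HighFidelitySet
from .kernel import sample_offspring
from .hitting import HittingMonitor
from .ssa import RateConstants, Trajectory, EventRecord, _choice


@dataclass
class Vesicle:
    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def contains(self, p: float) -> bool:
        return self.lo <= p <= self.hi


def check_nesting(vesicles: list[Vesicle]) -> None:
    """Vesicle intervals must be pairwise nested or disjoint."""
    for i, a in enumerate(vesicles):
        for b in vesicles[i + 1:]:
            if _crosses(a.lo, a.hi, b.lo, b.hi):
                raise RuntimeError("crossing vesicle intervals: invariant violated")


def _crosses(alo, ahi, blo, bhi) -> bool:
    overlap = max(alo, blo) < min(ahi, bhi)
    nested = (alo <= blo and bhi <= ahi) or (blo <= alo and ahi <= bhi)
    return overlap and not nested


def innermost_region(vesicles: list[Vesicle], p: float) -> int:
    """Index of the smallest vesicle containing p, or -1 (root)."""
    best, best_w = -1, np.inf
    for i, v in enumerate(vesicles):
        if v.contains(p) and v.width < best_w:
            best, best_w = i, v.width
    return best


class SpatialState:
    """Molecule-level population: parallel lists of codes and positions."""

    def __init__(self, space: SequenceSpace):
        self.space = space
        self.s_codes: list[int] = []
        self.s_pos: list[float] = []
        self.d_codes: list[int] = []   # canonical duplex codes
        self.d_pos: list[float] = []
        self.vesicles: list[Vesicle] = []

    @classmethod
    def from_codes(cls, space, codes, rng, T: float = 1.0) -> "SpatialState":
        st = cls(space)
        for c in codes:
            st.s_codes.append(int(c))
            st.s_pos.append(float(rng.uniform(-T, T)))
        return st

    @property
    def K(self) -> int:
        return len(self.s_codes) + len(self.d_codes)


def replicative_mass(state: SpatialState, landscape_tables,
                     a: float, restricted: bool = True) -> tuple[float, list]:
    """Total replication propensity; with ``restricted=True`` pairs are
    confined to common innermost vesicle regions.

    Returns (total, groups) where groups is a list of (indices, mass)
    per region for reactant selection.
    """
    fitness, similarity, s_diag = landscape_tables
    codes = np.asarray(state.s_codes, dtype=np.int64)
    if codes.size < 2:
        return 0.0, []
    if restricted and state.vesicles:
        regions = np.array([innermost_region(state.vesicles, p)
                            for p in state.s_pos])
    else:
        regions = np.zeros(codes.size, dtype=int)
    groups = []
    total = 0.0
    for r in np.unique(regions):
        idx = np.flatnonzero(regions == r)
        if idx.size < 2:
            continue
        c = codes[idx]
        f = fitness[c]
        S = similarity[np.ix_(c, c)]
        np.fill_diagonal(S, 0.0)  # a molecule cannot self-pair
        mass = a * float(f @ S.sum(axis=1))
        if mass > 0:
            groups.append((idx, mass))
            total += mass
    return total, groups


def simulate_spatial(space: SequenceSpace, landscape: Landscape,
                     R: HighFidelitySet, rates: RateConstants, init_codes,
                     budget: int, rng: np.random.Generator | int,
                     T: float = 1.0, vesicle_width: float = 0.5,
                     stop_on: str | None = None, v: float = 0.25,
                     record_events: bool = False) -> Trajectory:
    """SSA run with positions and vesicles; tracks restricted and
    unrestricted replicative mass at every event."""
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)

    state = SpatialState.from_codes(space, init_codes, rng, T)
    I = state.K
    fitness = landscape.fitness_vector(space, R)
    fidelity = landscape.fidelity_vector(space, R)
    similarity = landscape.similarity_matrix(space)
    tables = (fitness, similarity, np.diag(similarity).copy())
    R_set = set(int(c) for c in R.codes)
    Rc_set = R_set | {int(space.complement(c)) for c in R.codes}

    def vol_frac() -> float:
        if state.K == 0:
            return 0.0
        singles = sum(1 for c in state.s_codes if c in R_set)
        dups = sum(1 for c in state.d_codes
                   if c in R_set or int(space.complement(c)) in R_set)
        return (singles + dups) / state.K

    monitor = HittingMonitor(I=I, v=v)
    t = 0.0
    times, Ks, Vs = [0.0], [state.K], [vol_frac()]
    rep_series, rep_unres_series = [], []
    events: list = [] if record_events else None
    monitor.observe(0.0, state.K, Vs[0])

    rep_total, groups = replicative_mass(state, tables, rates.a)
    rep_unres, _ = replicative_mass(state, tables, rates.a, restricted=False)
    rep_series.append(rep_total)
    rep_unres_series.append(rep_unres)

    stopped_on = None
    n_done = 0
    for step in range(budget):
        ns = len(state.s_codes)
        # duplex formation: count complementary single pairs
        counts: dict[int, int] = {}
        for c in state.s_codes:
            counts[c] = counts.get(c, 0) + 1
        ds_rate = 0.5 * rates.kds * sum(
            cnt * counts.get(int(space.complement(c)), 0)
            for c, cnt in counts.items())
        ch = {
            "ds_form": ds_rate,
            "ds_dissoc": rates.kss * len(state.d_codes),
            "rna_poly": rep_total,
            "decay": rates.k_decay * ns,
            "clay_oligo": rates.k_clay_o,
            "clay_poly": rates.k_clay_p * ns,
            "vesiculate": rates.k_mic * ns,
        }
        names = list(ch)
        total = sum(ch.values())
        if total <= 0:
            stopped_on = "absorbing"
            break
        t += rng.exponential(1.0 / total)
        channel = names[_choice(rng, np.array([ch[c] for c in names]))]

        if channel == "ds_form":
            keys = list(counts)
            w = np.array([counts[c] * counts.get(int(space.complement(c)), 0)
                          for c in keys], dtype=float)
            x = keys[_choice(rng, w)]
            xc = int(space.complement(x))
            i = rng.choice([j for j, c in enumerate(state.s_codes) if c == x])
            j = rng.choice([j for j, c in enumerate(state.s_codes)
                            if c == xc and j != i])
            pos = state.s_pos[i]  # duplex keeps the first strand's position
            for k in sorted((int(i), int(j)), reverse=True):
                del state.s_codes[k]
                del state.s_pos[k]
            state.d_codes.append(min(x, xc))
            state.d_pos.append(pos)
        elif channel == "ds_dissoc":
            i = int(rng.integers(len(state.d_codes)))
            c, pos = state.d_codes.pop(i), state.d_pos.pop(i)
            state.s_codes += [c, int(space.complement(c))]
            state.s_pos += [pos, pos]
        elif channel == "rna_poly":
            gsel = _choice(rng, np.array([m for _, m in groups]))
            idx, _ = groups[gsel]
            c = np.asarray(state.s_codes)[idx]
            f = fitness[c]
            S = similarity[np.ix_(c, c)]
            np.fill_diagonal(S, 0.0)
            W = f[:, None] * S
            flat = _choice(rng, W.ravel())
            pi, ti = int(idx[flat // len(idx)]), int(idx[flat % len(idx)])
            z = sample_offspring(space, float(fidelity[state.s_codes[pi]]),
                                 state.s_codes[ti], rng)
            state.s_codes.append(z)
            state.s_pos.append(state.s_pos[ti])  # offspring at the template
        elif channel == "decay":
            i = int(rng.integers(ns))
            del state.s_codes[i]
            del state.s_pos[i]
        elif channel == "clay_oligo":
            state.s_codes.append(int(rng.integers(space.size)))
            state.s_pos.append(float(rng.uniform(-T, T)))
        elif channel == "clay_poly":
            i = int(rng.integers(ns))
            z = sample_offspring(space, rates.p_clay, state.s_codes[i], rng)
            state.s_codes.append(z)
            state.s_pos.append(state.s_pos[i])
        else:  # vesiculate
            i = int(rng.integers(ns))
            c = state.s_pos[i]
            lo = max(-T, c - vesicle_width / 2)
            hi = min(T, c + vesicle_width / 2)
            crossing = any(_crosses(lo, hi, vv.lo, vv.hi)
                           for vv in state.vesicles)
            if not crossing:
                state.vesicles.append(Vesicle(lo, hi))
                check_nesting(state.vesicles)

        n_done = step + 1
        rep_total, groups = replicative_mass(state, tables, rates.a)
        rep_unres, _ = replicative_mass(state, tables, rates.a,
                                        restricted=False)
        rep_series.append(rep_total)
        rep_unres_series.append(rep_unres)
        Vt = vol_frac()
        times.append(t)
        Ks.append(state.K)
        Vs.append(Vt)
        if record_events:
            events.append(EventRecord(n_done, t, channel, (), ()))
        monitor.observe(t, state.K, Vt)
        if stop_on is not None and monitor.fired(stop_on):
            stopped_on = stop_on
            break

    return Trajectory(
        n=space.n, I=I, budget=budget, seed=seed,
        times=np.asarray(times), K=np.asarray(Ks, dtype=np.int64),
        V=np.asarray(Vs), n_reactions=n_done, end_time=t,
        stopped_on=stopped_on, events=events,
        hitting=monitor.records(censor_time=t),
        rep_mass=np.asarray(rep_series),
        rep_mass_unrestricted=np.asarray(rep_unres_series),
    )
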