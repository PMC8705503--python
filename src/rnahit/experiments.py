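"""Experiment protocols: initialization, replicative-mass calibration,
parameter sweeps over (n, curvature, clay, decay), and the per-parameter
summaries g(theta) (finite-hit count) and f(theta) (mean finite hitting
time).

The core sweep crosses sequence dimension n in {3, 4} with five tent
curvature levels k = l = -log(i)/n, i in {0.1, 0.05, 0.01, 0.005, 0.001},
runs M = 10 replicates per cell with a 5000-reaction budget, and records
the volume-fraction hitting time tau_v (v = 0.1), right-censored at the
budget.  The replication scale a is calibrated per cell so the initial
replicative mass is exactly the target (10 for the core model;
(1 - f_clay) * 20 when clay polymerization shares the initial mass).

Seeding: every run draws its generator from a deterministic key
(base_seed, n, curvature index, draw index, replicate), so results are
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import SequenceSpace
from .landscapes import Landscape, HighFidelitySet, curvature_from_terminus
from .ssa import RateConstants, PopulationState, simulate

CORE_TERMINI = (0.1, 0.05, 0.01, 0.005, 0.001)


def init_population(space: SequenceSpace, I: int, rng: np.random.Generator,
                    R: HighFidelitySet | None = None,
                    avoid_R: bool = False) -> list[int]:
    """Draw I iid uniform single-strand sequences (duplicates allowed),
    optionally excluding the high-fidelity manifold."""
    if I < 1:
        raise ValueError("initial population size I must be >= 1")
    if avoid_R:
        if R is None:
            raise ValueError("avoid_R requires a high-fidelity set")
        if R.size >= space.size:
            raise ValueError("cannot avoid R: it covers all of E")
    codes = []
    while len(codes) < I:
        c = int(rng.integers(space.size))
        if avoid_R and c in R:
            continue
        codes.append(c)
    return codes


def unscaled_replicative_mass(space: SequenceSpace, landscape: Landscape,
                              R: HighFidelitySet, codes) -> float:
    """sum_{x,y} f(x) s(x,y) N(x)(N(y) - 1{x=y}) over the population."""
    state = PopulationState.from_codes(space, codes)
    Ns = state.Ns.astype(float)
    f = landscape.fitness_vector(space, R)
    S = landscape.similarity_matrix(space)
    rows = f * Ns * ((S @ Ns) - np.diag(S))
    return float(rows.sum())


def calibrate_replication_scale(space: SequenceSpace, landscape: Landscape,
                                R: HighFidelitySet, codes,
                                target: float) -> float:
    """Replication scale a making the initial total replication rate
    equal ``target`` exactly."""
    mass = unscaled_replicative_mass(space, landscape, R, codes)
    if mass <= 0:
        raise ValueError(
            "unscaled replicative mass is zero (e.g. a lone molecule); "
            "cannot calibrate the replication scale")
    return target / mass


def summarize(taus) -> tuple[int, float]:
    """g(theta): number of finite hitting times; f(theta): their mean
    (0 when there are none)."""
    finite = [t for t in taus if np.isfinite(t)]
    g = len(finite)
    return g, (float(np.mean(finite)) if g else 0.0)


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(list(key))


def run_core_sweep(base_seed: int, n_values=(3, 4), termini=CORE_TERMINI,
                   M: int = 10, budget: int = 5000, v: float = 0.1,
                   I: int = 10, target_mass: float = 10.0) -> pd.DataFrame:
    """Core-model sweep over (n, curvature); returns one row per run.

    R (a random singleton) and the initial population X0 (disjoint from
    R) are drawn once per n and reused across curvature levels, as the
    protocol fixes the search problem while the landscape varies.
    """
    rows = []
    for n in n_values:
        space = SequenceSpace(n)
        cell_rng = _rng(base_seed, n)
        R = HighFidelitySet.random_singleton(n, cell_rng)
        x0 = init_population(space, I, cell_rng, R=R, avoid_R=True)
        for ci, i_val in enumerate(termini):
            landscape = Landscape.tent_from_terminus(n, i_val)
            a = calibrate_replication_scale(space, landscape, R, x0,
                                            target_mass)
            rates = RateConstants(kds=1.0, kss=1.0, a=a)
            for rep in range(M):
                run_rng = _rng(base_seed, n, ci, rep)
                traj = simulate(space, landscape, R, rates, x0, budget,
                                run_rng, stop_on="tau_v", v=v)
                rec = traj.hitting["tau_v"]
                rows.append({
                    "n": n, "i": i_val,
                    "k": curvature_from_terminus(i_val, n),
                    "replicate": rep,
                    "tau": rec.value,
                    "censored": rec.censored,
                    "censor_time": rec.censor_time,
                    "n_reactions": traj.n_reactions,
                })
    return pd.DataFrame(rows)


def run_expanded_sweep(base_seed: int, n_values=(3, 4), termini=CORE_TERMINI,
                       draws_per_cell: int = 24, M: int = 10,
                       budget: int = 5000, v: float = 0.1, I: int = 10,
                       total_mass: float = 20.0) -> pd.DataFrame:
    """Clay-and-decay sweep: the (n, curvature) grid crossed with
    ``draws_per_cell`` iid Uniform(0,1)^3 draws of (k_decay, f_clay,
    p_clay) per cell.  The initial replicative mass is split between RNA
    polymerization, (1 - f_clay) * total_mass, and clay polymerization,
    f_clay * total_mass.  Default layout: 10 cells x 24 draws x 10
    replicates = 2400 runs."""
    rows = []
    for n in n_values:
        space = SequenceSpace(n)
        for ci, i_val in enumerate(termini):
            landscape = Landscape.tent_from_terminus(n, i_val)
            for d in range(draws_per_cell):
                draw_rng = _rng(base_seed, n, ci, d, 9999)
                k_decay = float(draw_rng.uniform())
                f_clay = float(draw_rng.uniform())
                p_clay = float(draw_rng.uniform())
                R = HighFidelitySet.random_singleton(n, draw_rng)
                x0 = init_population(space, I, draw_rng, R=R, avoid_R=True)
                a = calibrate_replication_scale(
                    space, landscape, R, x0, (1.0 - f_clay) * total_mass)
                rates = RateConstants(
                    kds=1.0, kss=1.0, a=a, k_decay=k_decay,
                    k_clay_o=1.0,
                    k_clay_p=f_clay * total_mass / I,
                    p_clay=max(p_clay, 1e-9),
                )
                for rep in range(M):
                    run_rng = _rng(base_seed, n, ci, d, rep)
                    traj = simulate(space, landscape, R, rates, x0, budget,
                                    run_rng, stop_on="tau_v", v=v)
                    rec = traj.hitting["tau_v"]
                    rows.append({
                        "n": n, "i": i_val,
                        "k": curvature_from_terminus(i_val, n),
                        "k_decay": k_decay, "f_clay": f_clay,
                        "p_clay": p_clay, "replicate": rep,
                        "tau": rec.value,
                        "censored": rec.censored,
                        "censor_time": rec.censor_time,
                        "n_reactions": traj.n_reactions,
                    })
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Per-theta summaries g (finite hits) and f (mean finite time)."""
    out = []
    for key, grp in df.groupby(by):
        g, f = summarize(grp["tau"].to_numpy())
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update(g=g, f=f, M=len(grp))
        out.append(row)
    return pd.DataFrame(out)
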