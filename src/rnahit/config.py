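"""YAML run configuration: schema validation, defaults, and construction
of the simulation objects.

A run config has sections ``space``, ``landscape``, ``manifold``,
``rates``, ``init``, ``stop``, ``compartments``, ``output`` and a top
level ``seed``.  Unknown keys are rejected with their field paths;
defaults follow the baseline parameterization (kss = kds = 1, replication
scale 10, fidelity terminus 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .sequences import SequenceSpace, SequenceError, encode
from .landscapes import Landscape, HighFidelitySet, curvature_from_terminus
from .ssa import RateConstants
from .experiments import init_population


class ConfigError(ValueError):
    """Schema violation(s) in a run configuration."""


_SCHEMA = {
    "space": {"n", "cap"},
    "landscape": {"form", "k", "l", "m", "fitness_terminus",
                  "similarity_terminus", "fidelity_terminus",
                  "similarity", "b"},
    "manifold": {"sequences", "fasta", "q", "singleton"},
    "rates": {"kds", "kss", "a", "target_initial_mass", "k_decay",
              "k_clay_o", "k_clay_p", "p_clay", "k_mic"},
    "init": {"I", "avoid_R", "sequences"},
    "stop": {"budget", "event", "v"},
    "compartments": {"enabled", "T", "vesicle_width"},
    "output": {"events", "measures_every", "fasta", "measures_csv",
               "hitting_csv", "events_jsonl"},
}
_TOP = set(_SCHEMA) | {"seed"}


@dataclass
class RunConfig:
    """Validated configuration plus constructed model objects."""

    n: int
    seed: int
    space: SequenceSpace
    landscape: Landscape
    manifold: HighFidelitySet
    rates: RateConstants
    init_codes: list[int]
    budget: int
    stop_event: str | None
    v: float
    compartments: dict
    output: dict
    raw: dict = field(repr=False, default_factory=dict)
    target_initial_mass: float | None = None


def load_config(path) -> RunConfig:
    """Load, validate, and materialize a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    errors = []
    for key in raw:
        if key not in _TOP:
            errors.append(f"unknown section '{key}'")
    for sec, allowed in _SCHEMA.items():
        for key in (raw.get(sec) or {}):
            if key not in allowed:
                errors.append(f"unknown key '{sec}.{key}'")

    sp = raw.get("space") or {}
    n = sp.get("n", 3)
    if not (isinstance(n, int) and n >= 1):
        errors.append("space.n must be a positive integer")
    ls = raw.get("landscape") or {}
    form = ls.get("form", "tent")
    if form not in ("tent", "linear"):
        errors.append("landscape.form must be 'tent' or 'linear'")
    for key in ("k", "l", "m"):
        if key in ls and not (np.isfinite(ls[key]) and ls[key] >= 0):
            errors.append(f"landscape.{key} must be a finite value >= 0")
    rt = raw.get("rates") or {}
    for key in ("kds", "kss", "a", "k_decay", "k_clay_o", "k_clay_p",
                "k_mic"):
        if key in rt and rt[key] < 0:
            errors.append(f"rates.{key} must be >= 0")
    st = raw.get("stop") or {}
    budget = st.get("budget", 5000)
    if not (isinstance(budget, int) and budget >= 0):
        errors.append("stop.budget must be a non-negative integer")
    mf = raw.get("manifold") or {}
    init = raw.get("init") or {}
    if init.get("avoid_R") and not mf:
        errors.append("init.avoid_R requires a manifold section")
    if errors:
        raise ConfigError("; ".join(errors))

    seed = int(raw.get("seed", 0))
    rng = np.random.default_rng(seed)
    space = SequenceSpace(n, cap=sp.get("cap", 8))

    # manifold
    if "sequences" in mf:
        manifold = HighFidelitySet.from_sequences(mf["sequences"])
    elif "fasta" in mf:
        manifold = HighFidelitySet.from_fasta(mf["fasta"])
    elif mf.get("singleton", True):
        manifold = HighFidelitySet.random_singleton(n, rng)
    else:
        manifold = HighFidelitySet.random_product(n, float(mf.get("q", 0.0)),
                                                  rng)
    if manifold.n != n:
        raise ConfigError("manifold sequence length differs from space.n")

    # landscape: explicit curvatures win; else terminus parameterization
    if form == "tent":
        k = ls.get("k", curvature_from_terminus(
            ls.get("fitness_terminus", 0.01), n))
        l = ls.get("l", curvature_from_terminus(
            ls.get("similarity_terminus", ls.get("fitness_terminus", 0.01)),
            n))
        m = ls.get("m", curvature_from_terminus(
            ls.get("fidelity_terminus", 0.25), n))
    else:
        k = ls.get("fitness_terminus", 0.01)
        l = ls.get("similarity_terminus", k)
        m = ls.get("fidelity_terminus", 0.25)
    landscape = Landscape(form=form, k=k, l=l, m=m,
                          similarity=ls.get("similarity", "distance"),
                          b=ls.get("b", 1.0))

    rates = RateConstants(
        kds=rt.get("kds", 1.0), kss=rt.get("kss", 1.0),
        a=rt.get("a", 10.0), k_decay=rt.get("k_decay", 0.0),
        k_clay_o=rt.get("k_clay_o", 0.0), k_clay_p=rt.get("k_clay_p", 0.0),
        p_clay=rt.get("p_clay", 0.9), k_mic=rt.get("k_mic", 0.0),
    )

    if "sequences" in init:
        init_codes = [encode(s) for s in init["sequences"]]
        if any(len(s) != n for s in init["sequences"]):
            raise ConfigError("init.sequences length differs from space.n")
    else:
        init_codes = init_population(space, int(init.get("I", 10)), rng,
                                     R=manifold,
                                     avoid_R=bool(init.get("avoid_R", False)))

    comp = raw.get("compartments") or {}
    return RunConfig(
        n=n, seed=seed, space=space, landscape=landscape, manifold=manifold,
        rates=rates, init_codes=init_codes, budget=budget,
        stop_event=st.get("event", "tau_v"), v=float(st.get("v", 0.25)),
        compartments={"enabled": bool(comp.get("enabled", False)),
                      "T": float(comp.get("T", 1.0)),
                      "vesicle_width": float(comp.get("vesicle_width", 0.5))},
        output=dict(raw.get("output") or {}),
        raw=raw,
        target_initial_mass=rt.get("target_initial_mass"),
    )
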