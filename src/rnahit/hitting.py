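"""Hitting-time detectors for the replicator process, with right censoring.

Four events are tracked:

* ``tau_rep`` — first replication: the first time the molecule count K
  exceeds the initial population size I;
* ``tau_R`` — first appearance of a high-fidelity sequence (free or
  inside a duplex);
* ``tau_min`` — the running minimum of the volume fraction V after
  tau_R: the time at which the high-fidelity lineage stops being diluted
  by the still-diversifying background;
* ``tau_v`` — first time V(t) >= v for a threshold v.

A run whose reaction budget ends before an event fires contributes a
right-censored record carrying the censor time (the trajectory end time).
Detectors exist in two equivalent forms: an online monitor used inside
the SSA loop (so runs can stop at the hit) and pure replay functions over
a logged trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class HittingRecord:
    """One hitting observation: a finite time or a censored flag with its
    censor time."""

    event: str
    time: Optional[float]          # None when censored
    censored: bool
    censor_time: Optional[float]   # trajectory end time when censored
    replicate: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.censored and self.time is not None:
            raise ValueError("censored record cannot carry a hitting time")
        if not self.censored and self.time is None:
            raise ValueError("non-censored record must carry a hitting time")

    @property
    def value(self) -> float:
        """The hitting time, or +inf when censored."""
        return math.inf if self.censored else float(self.time)


class HittingMonitor:
    """Online detector fed (t, K, V) after every event (and at t=0)."""

    EVENTS = ("tau_rep", "tau_R", "tau_min", "tau_v")

    def __init__(self, I: int, v: float, tau_min_mode: str = "last"):
        if not 0 <= v <= 1:
            raise ValueError("volume-fraction threshold v must be in [0, 1]")
        if tau_min_mode not in ("last", "first"):
            raise ValueError("tau_min_mode must be 'last' or 'first'")
        self.I = I
        self.v = v
        self.tau_min_mode = tau_min_mode
        self.tau_rep: Optional[float] = None
        self.tau_R: Optional[float] = None
        self.tau_v: Optional[float] = None
        self._vmin: Optional[float] = None
        self._tmin: Optional[float] = None

    def observe(self, t: float, K: int, V: float) -> None:
        if self.tau_rep is None and K > self.I:
            self.tau_rep = t
        if self.tau_R is None and V > 0:
            self.tau_R = t
        if self.tau_R is not None:
            better = self._vmin is None or (
                V < self._vmin if self.tau_min_mode == "first" else V <= self._vmin
            )
            if better:
                self._vmin, self._tmin = V, t
        if self.tau_v is None and V >= self.v:
            self.tau_v = t

    def fired(self, event: str) -> bool:
        if event == "tau_min":
            return self._tmin is not None
        return getattr(self, event) is not None

    def records(self, censor_time: float) -> dict:
        out = {}
        for ev, val in (("tau_rep", self.tau_rep), ("tau_R", self.tau_R),
                        ("tau_min", self._tmin), ("tau_v", self.tau_v)):
            if val is None:
                out[ev] = HittingRecord(ev, None, True, censor_time)
            else:
                out[ev] = HittingRecord(ev, val, False, None)
        return out


def volume_fraction(state, R_codes) -> float:
    """V(t): fraction of molecules that are high-fidelity singles or
    duplexes containing a high-fidelity strand."""
    K = state.K
    if K <= 0:
        raise ValueError("volume fraction undefined for an empty population")
    R_codes = np.atleast_1d(np.asarray(R_codes, dtype=np.int64))
    singles = int(state.Ns[R_codes].sum())
    canon = np.unique(np.minimum(R_codes, state.space.complement(R_codes)))
    dups = int(state.Nd[canon].sum())
    return (singles + dups) / K


def _replay(trajectory, v: float, tau_min_mode: str = "last") -> dict:
    """Recompute all hitting records from a trajectory's logged
    (times, K, V) series.  Pure function of the log."""
    mon = HittingMonitor(I=trajectory.I, v=v, tau_min_mode=tau_min_mode)
    for t, K, V in zip(trajectory.times, trajectory.K, trajectory.V):
        mon.observe(float(t), int(K), float(V))
    return mon.records(censor_time=float(trajectory.end_time))


def detect_tau_rep(trajectory) -> HittingRecord:
    """First time the molecule count exceeds the initial size I."""
    return _replay(trajectory, v=1.0)["tau_rep"]


def detect_tau_R(trajectory) -> HittingRecord:
    """First time any high-fidelity member is present (V > 0)."""
    return _replay(trajectory, v=1.0)["tau_R"]


def detect_tau_min(trajectory, mode: str = "last") -> HittingRecord:
    """Time of the running minimum of V on [tau_R, end]; ``mode`` picks
    the last (default) or first attainment of the minimum."""
    return _replay(trajectory, v=1.0, tau_min_mode=mode)["tau_min"]


def detect_tau_v(trajectory, v: float) -> HittingRecord:
    """First time V(t) >= v; censored at the trajectory end otherwise."""
    return _replay(trajectory, v=v)["tau_v"]


def hitting_table(records: list[HittingRecord], theta: dict | None = None):
    """Tabulate hitting records as a DataFrame (one row per record) with
    optional parameter-vector columns."""
    import pandas as pd

    rows = []
    for r in records:
        row = dict(theta or {})
        row.update(event=r.event, time=r.time, censored=r.censored,
                   censor_time=r.censor_time, replicate=r.replicate,
                   seed=r.seed)
        rows.append(row)
    return pd.DataFrame(rows)
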