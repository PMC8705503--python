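"""Mean-field ODE reduction of the reaction network.

Mass-action rate equations for the molecule-count coordinates [x]
(single strands) and [{x,xc}] (duplexes), assembled from the same
propensities as the stochastic model — in particular the replication
term keeps the self-pair exclusion [x]([y] - 1{x=y}), so a lone
high-fidelity molecule cannot copy itself:

    d[z]/dt = -kds [z][zc] + kss [{z,zc}]
              + sum_{x,y} a f(x) s(x,y) [x]([y] - 1{x=y}) Q((x,y),{z})
    d[{c,cc}]/dt = kds [c][cc] - kss [{c,cc}]

For a singleton high-fidelity set R = {x*} (tent landscapes, perfect
fidelity on R) the state with [x*] = 1 and every other coordinate 0 is
an equilibrium; its Jacobian has no zero eigenvalue and at least one
positive one, so the equilibrium is unstable — any perturbation (a
second molecule) launches unbounded growth.  Decay and clay channels
are excluded by default and can be switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import SequenceSpace, SequenceError
from .landscapes import Landscape, HighFidelitySet
from .ssa import RateConstants

_MEANFIELD_CAP = 3  # dense Q tensor is 4^n x 4^n x 4^n


class MeanFieldODE:
    """Mass-action ODE system over singles and duplexes.

    State vector: first 4^n single-strand coordinates, then 4^n/2 duplex
    coordinates (canonical codes c < cc), dimension 3*4^n/2.
    """

    def __init__(self, space: SequenceSpace, landscape: Landscape,
                 R: HighFidelitySet, rates: RateConstants,
                 include_decay: bool = False, include_clay: bool = False):
        if space.n > _MEANFIELD_CAP:
            raise SequenceError(
                f"mean-field reduction is dense in 4^n; n <= {_MEANFIELD_CAP}")
        self.space = space
        self.rates = rates
        self.include_decay = include_decay
        self.include_clay = include_clay
        D = space.size
        self.D = D
        self.perm = space.complement_perm
        self.canonical = np.flatnonzero(space.codes() < self.perm)
        self.can_index = np.full(D, -1)
        self.can_index[self.canonical] = np.arange(D // 2)
        # duplex slot of a single-strand code
        self.dup_of = self.can_index[np.minimum(space.codes(), self.perm)]
        self.dim = D + D // 2

        self.f = landscape.fitness_vector(space, R)
        self.p = landscape.fidelity_vector(space, R)
        self.S = landscape.similarity_matrix(space)
        # offspring tensor Q[x, y, z] = P(offspring z | polymerase x, template y)
        d = space.hamming_table[self.perm]          # d[y, z] = h(yc, z)
        n = space.n
        Q = np.empty((D, D, D))
        for x in range(D):
            px = self.p[x]
            if px >= 1.0:
                coef = np.zeros(n + 1)
                coef[0] = 1.0
            else:
                i = np.arange(n + 1)
                coef = (px ** (n - i)) * (((1 - px) / 3.0) ** i)
            Q[x] = coef[d]
        self.Q = Q
        self.labels = (
            [f"ss:{c}" for c in range(D)]
            + [f"ds:{c}" for c in self.canonical]
        )

    # -- vector field ----------------------------------------------------

    def _pair_rate(self, s: np.ndarray) -> np.ndarray:
        """M[x,y] = a f(x) s(x,y) [x]([y] - 1{x=y})."""
        M = self.rates.a * self.f[:, None] * self.S * np.outer(s, s)
        M[np.diag_indices(self.D)] -= \
            self.rates.a * self.f * np.diag(self.S) * s
        return M

    def rhs(self, v: np.ndarray) -> np.ndarray:
        s, w = v[:self.D], v[self.D:]
        r = self.rates
        wd = w[self.dup_of]          # duplex coordinate feeding each strand
        ds_pair = s * s[self.perm]
        F_s = -r.kds * ds_pair + r.kss * wd
        F_s = F_s + np.einsum("xy,xyz->z", self._pair_rate(s), self.Q)
        if self.include_decay:
            F_s = F_s - r.k_decay * s
        if self.include_clay:
            F_s = F_s + r.k_clay_o / self.D
            F_s = F_s + r.k_clay_p * np.einsum(
                "x,xz->z", s, self.Q[np.arange(self.D), np.arange(self.D)])
        F_d = r.kds * ds_pair[self.canonical] - r.kss * w
        return np.concatenate([F_s, F_d])

    def jacobian(self, v: np.ndarray) -> np.ndarray:
        s, w = v[:self.D], v[self.D:]
        r = self.rates
        D = self.D
        J = np.zeros((self.dim, self.dim))
        # duplex-formation terms
        for z in range(D):
            zc = int(self.perm[z])
            J[z, z] += -r.kds * s[zc]
            J[z, zc] += -r.kds * s[z]
            J[z, D + self.dup_of[z]] += r.kss
        for ci, c in enumerate(self.canonical):
            cc = int(self.perm[c])
            J[D + ci, c] += r.kds * s[cc]
            J[D + ci, cc] += r.kds * s[c]
            J[D + ci, D + ci] += -r.kss
        # replication: d/ds_w of sum_{x,y} a f s Q [x]([y]-1xy)
        fw = self.rates.a * self.f
        sy = s[None, :] - np.eye(D)  # (x, y): [y] - 1{x=y}
        A = np.einsum("wy,wyz->wz", fw[:, None] * self.S * sy, self.Q)
        # B[w,z] = sum_x a f(x) S(x,w) s_x Q[x,w,z]
        B = np.einsum("xw,xwz->wz", (fw * s)[:, None] * self.S, self.Q)
        J[:D, :D] += (A + B).T
        if self.include_decay:
            J[:D, :D] -= r.k_decay * np.eye(D)
        if self.include_clay:
            Jc = self.Q[np.arange(D), np.arange(D)]  # (x, z)
            J[:D, :D] += r.k_clay_p * Jc.T
        return J

    # -- equilibria ------------------------------------------------------

    def pure_state(self, code: int, amount: float = 1.0) -> np.ndarray:
        """State with ``amount`` of single strand ``code`` and 0 elsewhere."""
        v = np.zeros(self.dim)
        v[int(code)] = amount
        return v

    def residual(self, v: np.ndarray) -> float:
        return float(np.linalg.norm(self.rhs(v), ord=np.inf))

    def find_fixed_point(self, start: np.ndarray, tol: float = 1e-13,
                         maxiter: int = 100) -> np.ndarray:
        """Newton iteration on the full vector field from ``start``."""
        v = np.asarray(start, dtype=float).copy()
        for _ in range(maxiter):
            F = self.rhs(v)
            if np.linalg.norm(F, ord=np.inf) < tol:
                return v
            step = np.linalg.lstsq(self.jacobian(v), -F, rcond=None)[0]
            v = v + step
        raise RuntimeError("Newton iteration did not converge to a fixed point")

    def stability(self, v: np.ndarray, zero_tol: float = 1e-10) -> dict:
        """Eigenvalues of the Jacobian at v and a classification."""
        eig = np.linalg.eigvals(self.jacobian(v))
        has_zero = bool(np.any(np.abs(eig) < zero_tol))
        n_pos = int(np.sum(eig.real > zero_tol))
        return {
            "eigenvalues": eig,
            "has_zero_eigenvalue": has_zero,
            "n_positive": n_pos,
            "classification": "unstable" if n_pos else "stable-or-neutral",
        }

    def integrate(self, v0: np.ndarray, t_span: tuple[float, float],
                  **kw):
        from scipy.integrate import solve_ivp
        return solve_ivp(lambda t, v: self.rhs(v), t_span, v0,
                         jac=lambda t, v: self.jacobian(v),
                         method="LSODA", **kw)


def fixed_point_report(n: int = 2, seed: int = 0,
                               terminus: float = 0.01) -> dict:
    """Build the core-model mean-field system with a random singleton R,
    locate the non-trivial equilibrium by Newton iteration from a
    perturbed start, and report its high-fidelity coordinate, residual,
    and Jacobian spectrum."""
    rng = np.random.default_rng(seed)
    space = SequenceSpace(n)
    R = HighFidelitySet.random_singleton(n, rng)
    landscape = Landscape.tent_from_terminus(n, terminus)
    ode = MeanFieldODE(space, landscape, R, RateConstants(a=10.0))
    xstar = int(R.codes[0])
    start = ode.pure_state(xstar, 1.0)
    start = start + 1e-3 * rng.random(ode.dim)
    fp = ode.find_fixed_point(start)
    stab = ode.stability(fp)
    return {
        "n": n,
        "high_fidelity_code": xstar,
        "fixed_point": fp,
        "high_fidelity_concentration": float(fp[xstar]),
        "residual": ode.residual(fp),
        "n_positive_eigenvalues": stab["n_positive"],
        "has_zero_eigenvalue": stab["has_zero_eigenvalue"],
        "classification": stab["classification"],
        "eigenvalues": stab["eigenvalues"],
    }
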