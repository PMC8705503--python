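"""High dimensional model representation (HDMR) with variance-based
sensitivity indices.

The input-output map y = f(theta_1, ..., theta_d) is expanded as

    f = f0 + sum_i f_i(theta_i) + sum_{i<j} f_ij(theta_i, theta_j) + ...

with mean-zero component functions that are mutually orthogonal under
the (product) input measure.  The variance of f then decomposes as
sigma_f^2 = sum_u sigma_u^2 and the normalized shares
S_u = sigma_u^2 / sigma_f^2 are the sensitivity indices.

Estimation is least squares on basis expansions: gridded/discrete inputs
get centered indicator contrasts; continuous inputs get shifted-Legendre
polynomials (degree <= 3 by default).  Each input's basis is empirically
centered and orthonormalized (QR), so with an independent sampling
design the first- and second-order blocks are near-orthogonal and the
fitted block variances reconstruct the explained variance.

Two front-ends mirror the hitting-time analyses: ``classify_hitting``
expands the 0/1 finite-hit indicator (an ANOVA of hitting probability)
and ``regress_hitting_time`` expands the hitting time on the finite-hit
subsample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

_RANK_TOL = 1e-9


class _InputBasis:
    """Mean-zero orthonormalized basis functions of one input."""

    def __init__(self, name: str, values: np.ndarray, kind: str,
                 degree: int = 3):
        self.name = name
        self.kind = kind
        x = np.asarray(values)
        if kind == "discrete":
            self.levels = np.unique(x)
            raw = self._raw_discrete(x)
        else:
            self.lo, self.hi = float(np.min(x)), float(np.max(x))
            if self.hi <= self.lo:
                raw = np.empty((x.size, 0))
            else:
                deg = min(degree, len(np.unique(x)) - 1)
                raw = self._raw_continuous(x.astype(float), deg)
        self.degree = raw.shape[1]
        self._mean = raw.mean(axis=0) if raw.size else np.empty(0)
        centered = raw - self._mean
        if centered.shape[1] == 0:
            self._T = np.empty((0, 0))
            self.columns = np.empty((x.size, 0))
            return
        q, r = np.linalg.qr(centered)
        keep = np.abs(np.diag(r)) > _RANK_TOL * max(1.0, np.abs(r).max())
        if not keep.all():
            warnings.warn(f"rank-deficient basis for input {name}; "
                          f"truncated to {int(keep.sum())} functions")
        rk = r[np.ix_(keep, keep)]
        self._T = np.zeros((centered.shape[1], int(keep.sum())))
        self._T[keep] = np.linalg.inv(rk)
        self.columns = centered @ self._T

    def _raw_discrete(self, x) -> np.ndarray:
        # indicators for all but the last level
        return np.column_stack([(x == lv).astype(float)
                                for lv in self.levels[:-1]]) \
            if len(self.levels) > 1 else np.empty((x.size, 0))

    def _raw_continuous(self, x, deg) -> np.ndarray:
        z = 2.0 * (x - self.lo) / (self.hi - self.lo) - 1.0  # [-1, 1]
        cols = []
        for d in range(1, deg + 1):
            c = np.zeros(d + 1)
            c[d] = 1.0
            cols.append(np.polynomial.legendre.legval(z, c))
        return np.column_stack(cols) if cols else np.empty((x.size, 0))

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the orthonormalized basis at new input values."""
        x = np.asarray(x)
        if self.kind == "discrete":
            raw = np.column_stack([(x == lv).astype(float)
                                   for lv in self.levels[:-1]]) \
                if len(self.levels) > 1 else np.empty((x.size, 0))
        else:
            raw = self._raw_continuous(x.astype(float), len(self._mean))
        return (raw - self._mean) @ self._T


@dataclass
class HDMRResults:
    """Fitted HDMR expansion: constant f0, per-group sensitivity indices,
    and evaluable component functions."""

    f0: float
    sigma2: dict
    total_variance: float
    explained_variance: float     # Var(fitted) / Var(y)
    component_fitted: dict = field(repr=False, default_factory=dict)
    _bases: dict = field(repr=False, default_factory=dict)
    _coefs: dict = field(repr=False, default_factory=dict)

    @property
    def indices(self) -> dict:
        """Sensitivity indices S_u = sigma_u^2 / Var(y)."""
        if self.total_variance <= 0:
            return {u: 0.0 for u in self.sigma2}
        return {u: s / self.total_variance for u, s in self.sigma2.items()}

    def index(self, u) -> float:
        return self.indices[u]

    def component(self, name: str, x) -> np.ndarray:
        """Evaluate a first-order component function at input values.
        Inputs with no variation have the zero component."""
        basis = self._bases[name]
        if name not in self._coefs:
            return np.zeros(np.asarray(x).size)
        return basis.evaluate(x) @ self._coefs[name]

    def component_pair(self, name_i: str, name_j: str, xi, xj) -> np.ndarray:
        bi, bj = self._bases[name_i], self._bases[name_j]
        zi, zj = bi.evaluate(xi), bj.evaluate(xj)
        prod = (zi[:, :, None] * zj[:, None, :]).reshape(len(zi), -1)
        mean, coef = self._coefs[(name_i, name_j)]
        return (prod - mean) @ coef

    def summary(self) -> pd.DataFrame:
        rows = [{"term": str(u), "sigma2": s, "S": self.indices[u]}
                for u, s in self.sigma2.items()]
        df = pd.DataFrame(rows)
        df.attrs["f0"] = self.f0
        df.attrs["explained_variance"] = self.explained_variance
        return df

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "indices": {"|".join(u) if isinstance(u, tuple) else u: float(s)
                        for u, s in self.indices.items()},
            "explained_variance": float(self.explained_variance),
            "total_variance": float(self.total_variance),
        }


class HDMR:
    """HDMR expansion of observations (theta, y) up to second order.

    Parameters
    ----------
    X : DataFrame
        Input samples, one column per parameter, drawn from (or weighted
        to) a product measure.
    y : array-like
        Outputs (continuous or 0/1).
    order : int
        Expansion order (1 or 2).
    degree : int
        Maximum polynomial degree for continuous inputs.
    kinds : dict, optional
        Per-column override, "discrete" or "continuous"; by default a
        column with at most 10 distinct values is treated as discrete
        (gridded).
    """

    MIN_SAMPLES = 50

    def __init__(self, X: pd.DataFrame, y, order: int = 2, degree: int = 3,
                 kinds: dict | None = None, min_samples: int | None = None):
        if order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        self.X = pd.DataFrame(X)
        self.y = np.asarray(y, dtype=float)
        lim = self.MIN_SAMPLES if min_samples is None else min_samples
        if self.y.size < lim:
            raise ValueError(f"need at least {lim} samples, got {self.y.size}")
        self.order = order
        self.degree = degree
        self.kinds = {}
        for col in self.X.columns:
            if kinds and col in kinds:
                self.kinds[col] = kinds[col]
            else:
                vals = self.X[col]
                self.kinds[col] = ("discrete"
                                   if vals.nunique() <= 10 else "continuous")

    def fit(self) -> HDMRResults:
        y = self.y
        f0 = float(y.mean())
        total_var = float(y.var())
        names = list(self.X.columns)
        bases = {c: _InputBasis(c, self.X[c].to_numpy(), self.kinds[c],
                                self.degree) for c in names}

        blocks: dict = {}
        for c in names:
            if bases[c].columns.shape[1]:
                blocks[c] = bases[c].columns
        pair_meta = {}
        if self.order >= 2:
            for ci, cj in combinations(names, 2):
                zi, zj = bases[ci].columns, bases[cj].columns
                if zi.shape[1] == 0 or zj.shape[1] == 0:
                    continue
                prod = (zi[:, :, None] * zj[:, None, :]).reshape(len(y), -1)
                mean = prod.mean(axis=0)
                blocks[(ci, cj)] = prod - mean
                pair_meta[(ci, cj)] = mean

        if not blocks or total_var <= 0:
            return HDMRResults(f0, {u: 0.0 for u in blocks}, total_var,
                               0.0, {}, bases, {})

        design = np.column_stack(list(blocks.values()))
        coef, *_ = np.linalg.lstsq(design, y - f0, rcond=None)

        sigma2, comp_fitted, coefs = {}, {}, {}
        pos = 0
        for u, B in blocks.items():
            k = B.shape[1]
            cu = coef[pos:pos + k]
            fu = B @ cu
            sigma2[u] = float(np.mean(fu**2))
            comp_fitted[u] = fu
            coefs[u] = (pair_meta[u], cu) if isinstance(u, tuple) else cu
            pos += k
        fitted = design @ coef
        explained = float(fitted.var() / total_var)
        return HDMRResults(f0, sigma2, total_var, explained,
                           comp_fitted, bases, coefs)


def classify_hitting(df: pd.DataFrame, inputs: list[str],
                     order: int = 2, **kw) -> HDMRResults:
    """HDMR of the per-run finite-hit indicator: a variance decomposition
    of hitting probability over the swept parameters."""
    y = np.isfinite(df["tau"].to_numpy()).astype(float)
    return HDMR(df[inputs], y, order=order, **kw).fit()


def regress_hitting_time(df: pd.DataFrame, inputs: list[str],
                         order: int = 2, **kw) -> HDMRResults:
    """HDMR of the hitting time on the finite-hit subsample (the
    conditioning on hitting is part of the analysis design)."""
    finite = df[np.isfinite(df["tau"])]
    return HDMR(finite[inputs], finite["tau"].to_numpy(),
                order=order, **kw).fit()
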