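"""Penalized least-squares base-learners for component-wise boosting.

Five kinds are available:

* ``intercept`` -- a constant column, unpenalized;
* ``linear``    -- one centered covariate column, unpenalized (the
  per-parameter intercept learner absorbs the level, so linear learners
  carry no intercept of their own);
* ``pspline``   -- cubic B-spline basis on 20 equidistant interior knots
  with a second-order difference penalty;
* ``varying``   -- a P-spline basis multiplied elementwise by a binary
  effect-modifier column (varying-coefficient term);
* ``tensor``    -- a two-dimensional P-spline: row-wise Kronecker product of
  two marginal bases with penalty P1 (x) I + I (x) P2 and a single
  smoothing parameter;
* ``mrf``       -- Markov random field over discrete region labels: region
  indicator matrix with the graph-Laplacian penalty of an adjacency list.

Multi-column learners are calibrated, once and before boosting, to a common
effective degrees of freedom (default 4) by solving
trace(X (X'X + lambda P)^-1 X') = df for lambda, so that base-learner
selection compares components of equal flexibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = ["LearnerSpec", "BaseLearner", "build_learner", "mrf_laplacian", "calibrate_penalty"]


@dataclass
class LearnerSpec:
    kind: str  # intercept | linear | pspline | varying | tensor | mrf
    covariates: tuple = ()
    by: str | None = None  # binary modifier column (varying)
    knots: int = 20
    degree: int = 3
    penalty_order: int = 2
    df: float = 4.0
    name: str = ""

    def __post_init__(self):
        if isinstance(self.covariates, str):
            self.covariates = (self.covariates,)
        else:
            self.covariates = tuple(self.covariates)
        if self.kind not in ("intercept", "linear", "pspline", "varying", "tensor", "mrf"):
            raise ValueError(f"unknown learner kind '{self.kind}'")
        if self.knots < self.penalty_order + 1:
            raise ValueError("need knots >= penalty_order + 1")
        if not self.name:
            base = ",".join(self.covariates) if self.covariates else "1"
            self.name = f"{self.kind}({base})" + (f":{self.by}" if self.by else "")


def _diff_penalty(L, order):
    D = np.diff(np.eye(L), n=order, axis=0)
    return D.T @ D


def _spline_knots(x, n_interior, degree):
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1e-8
    step = (hi - lo) / (n_interior + 1)
    return np.linspace(lo - degree * step, hi + degree * step, n_interior + 2 + 2 * degree)


def _spline_design(x, knots, degree):
    lo, hi = knots[degree], knots[-degree - 1]
    xc = np.clip(np.asarray(x, float), lo, hi)  # new data clipped to training range
    return BSpline.design_matrix(xc, knots, degree).toarray()


def mrf_laplacian(levels, adjacency):
    """Graph Laplacian over region ``levels`` from an edge list of label
    pairs.  Edges mentioning unobserved labels are ignored; isolated
    regions trigger a warning (their effect is penalized towards zero
    only through the boosting shrinkage)."""
    index = {lab: i for i, lab in enumerate(levels)}
    R = len(levels)
    Lap = np.zeros((R, R))
    for a, b in adjacency:
        if a in index and b in index and a != b:
            i, j = index[a], index[b]
            if Lap[i, j] == 0.0:
                Lap[i, j] = Lap[j, i] = -1.0
    np.fill_diagonal(Lap, 0.0)
    deg = -Lap.sum(axis=1)
    np.fill_diagonal(Lap, deg)
    if np.any(deg == 0) and R > 1:
        warnings.warn("MRF: some regions have no neighbours (disconnected graph)")
    return Lap


def calibrate_penalty(X, P, df):
    """Smoothing parameter lambda with trace of the ridge hat matrix = df."""
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    nullity = P.shape[0] - np.linalg.matrix_rank(P)

    def edf(lam):
        return float(np.trace(linalg.solve(XtX + lam * P + 1e-12 * np.eye(len(P)), XtX)))

    if df > rank + 1e-8:
        raise ValueError(f"target df {df} exceeds design rank {rank}")
    if abs(df - rank) < 1e-8:
        return 0.0
    if df < nullity - 1e-8:
        raise ValueError(f"target df {df} below penalty null space dimension {nullity}")
    lo, hi = 1e-10, 1e12
    while edf(hi) > df and hi < 1e15:
        hi *= 100
    loglam = brentq(lambda ll: edf(np.exp(ll)) - df, np.log(lo), np.log(hi), xtol=1e-13)
    return float(np.exp(loglam))


class BaseLearner:
    """A design matrix + penalty, prepared on the training data, that can be
    refit cheaply to successive pseudo-residual vectors."""

    def __init__(self, spec: LearnerSpec, data: pd.DataFrame, adjacency=None):
        self.spec = spec
        self.state: dict = {}
        X, P = self._build(spec, data, adjacency)
        self.X = X
        self.P = P
        self.n_coef = X.shape[1]
        if spec.kind in ("intercept", "linear"):
            self.lam = 0.0
        else:
            # the hat-matrix trace is bounded below by the penalty null-space
            # dimension (4 for a tensor P-spline with second-order penalties),
            # so the target df is raised just above it when necessary
            nullity = P.shape[0] - np.linalg.matrix_rank(P)
            df = min(max(spec.df, nullity + 1.0), np.linalg.matrix_rank(X.T @ X))
            self.lam = calibrate_penalty(X, P, df)
        A = X.T @ X + self.lam * P
        try:
            self._chol = linalg.cho_factor(A)
        except linalg.LinAlgError:
            warnings.warn(f"singular design for learner {spec.name}; adding ridge jitter")
            self._chol = linalg.cho_factor(A + 1e-8 * np.eye(self.n_coef))

    # -- construction -----------------------------------------------------------
    def _build(self, spec, data, adjacency):
        if spec.kind == "intercept":
            return np.ones((len(data), 1)), np.zeros((1, 1))
        if spec.kind == "linear":
            col = self._col(data, spec.covariates[0])
            center = float(np.mean(col))
            self.state["center"] = center
            return (col - center)[:, None], np.zeros((1, 1))
        if spec.kind in ("pspline", "varying"):
            col = self._col(data, spec.covariates[0])
            knots = _spline_knots(col, spec.knots, spec.degree)
            self.state["knots"] = knots
            X = _spline_design(col, knots, spec.degree)
            P = _diff_penalty(X.shape[1], spec.penalty_order)
            if spec.kind == "varying":
                X = X * self._col(data, spec.by)[:, None]
            return X, P
        if spec.kind == "tensor":
            c1 = self._col(data, spec.covariates[0])
            c2 = self._col(data, spec.covariates[1])
            nk = spec.knots if spec.knots != 20 else 5  # per-dimension default
            k1 = _spline_knots(c1, nk, spec.degree)
            k2 = _spline_knots(c2, nk, spec.degree)
            self.state["knots"] = (k1, k2)
            B1 = _spline_design(c1, k1, spec.degree)
            B2 = _spline_design(c2, k2, spec.degree)
            X = (B1[:, :, None] * B2[:, None, :]).reshape(len(c1), -1)
            P1 = _diff_penalty(B1.shape[1], spec.penalty_order)
            P2 = _diff_penalty(B2.shape[1], spec.penalty_order)
            P = np.kron(P1, np.eye(B2.shape[1])) + np.kron(np.eye(B1.shape[1]), P2)
            return X, P
        if spec.kind == "mrf":
            if adjacency is None:
                raise ValueError("mrf learner requires an adjacency edge list")
            labels = data[spec.covariates[0]].astype(str).to_numpy()
            levels = sorted(set(labels))
            self.state["levels"] = levels
            X = (labels[:, None] == np.array(levels)[None, :]).astype(float)
            P = mrf_laplacian(levels, adjacency)
            return X, P
        raise AssertionError

    @staticmethod
    def _col(data, name):
        if name not in data.columns:
            raise KeyError(f"covariate '{name}' not found in data")
        return data[name].to_numpy(dtype=float)

    # -- fitting ------------------------------------------------------------------
    def fit(self, u):
        """Penalized least-squares fit to pseudo-residuals u; returns
        (coef, rss)."""
        Xtu = self.X.T @ u
        coef = linalg.cho_solve(self._chol, Xtu)
        resid = u - self.X @ coef
        return coef, float(resid @ resid)

    # -- prediction ------------------------------------------------------------------
    def design(self, data: pd.DataFrame):
        """Design matrix on new data (training transforms frozen)."""
        spec = self.spec
        if spec.kind == "intercept":
            return np.ones((len(data), 1))
        if spec.kind == "linear":
            return (self._col(data, spec.covariates[0]) - self.state["center"])[:, None]
        if spec.kind in ("pspline", "varying"):
            X = _spline_design(self._col(data, spec.covariates[0]), self.state["knots"], spec.degree)
            if spec.kind == "varying":
                X = X * self._col(data, spec.by)[:, None]
            return X
        if spec.kind == "tensor":
            k1, k2 = self.state["knots"]
            B1 = _spline_design(self._col(data, spec.covariates[0]), k1, spec.degree)
            B2 = _spline_design(self._col(data, spec.covariates[1]), k2, spec.degree)
            return (B1[:, :, None] * B2[:, None, :]).reshape(len(data), -1)
        if spec.kind == "mrf":
            labels = data[spec.covariates[0]].astype(str).to_numpy()
            levels = np.array(self.state["levels"])
            unseen = ~np.isin(labels, levels)
            if unseen.any():
                warnings.warn(
                    f"MRF: {int(unseen.sum())} observations in unseen regions; "
                    "their spatial contribution is set to zero"
                )
            return (labels[:, None] == levels[None, :]).astype(float)
        raise AssertionError

    def predict(self, data, coef):
        return self.design(data) @ coef

    # -- serialization -----------------------------------------------------------------
    def to_dict(self):
        state = {}
        for k, v in self.state.items():
            if k == "knots" and isinstance(v, tuple):
                state[k] = [vv.tolist() for vv in v]
            elif isinstance(v, np.ndarray):
                state[k] = v.tolist()
            else:
                state[k] = v
        return {
            "spec": {
                "kind": self.spec.kind,
                "covariates": list(self.spec.covariates),
                "by": self.spec.by,
                "knots": self.spec.knots,
                "degree": self.spec.degree,
                "penalty_order": self.spec.penalty_order,
                "df": self.spec.df,
                "name": self.spec.name,
            },
            "state": state,
            "lam": self.lam,
            "n_coef": self.n_coef,
        }

    @classmethod
    def from_dict(cls, d):
        """Prediction-only reconstruction (no training design)."""
        obj = cls.__new__(cls)
        kw = dict(d["spec"])
        kw["covariates"] = tuple(kw["covariates"])
        obj.spec = LearnerSpec(**kw)
        obj.n_coef = d["n_coef"]
        state = dict(d["state"])
        if "knots" in state:
            v = state["knots"]
            if v and isinstance(v[0], list):
                state["knots"] = tuple(np.asarray(vv, float) for vv in v)
            else:
                state["knots"] = np.asarray(v, float)
        obj.state = state
        obj.lam = d["lam"]
        obj.X = obj.P = obj._chol = None
        return obj


def build_learner(spec: LearnerSpec, data: pd.DataFrame, adjacency=None) -> BaseLearner:
    return BaseLearner(spec, data, adjacency)
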