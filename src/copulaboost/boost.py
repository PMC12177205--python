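"""Non-cyclical component-wise gradient boosting for distributional copula
regression.

Every distribution parameter (margin parameters and the copula dependence
parameter) has its own additive predictor and its own set of base-learners.
Each iteration:

1. computes the negative gradient of the empirical risk (the mean negative
   joint log-likelihood) with respect to every predictor, L2-stabilised so
   effective step lengths are comparable across parameters;
2. fits every base-learner of every parameter to its parameter's gradient
   and keeps, within each parameter, the learner with the smallest residual
   sum of squares;
3. evaluates the realized risk reduction of the K candidate updates
   (step_length times the fitted learner) and commits only the single best
   one (ties broken by parameter order, then learner registration order).

The stopping iteration is tuned on a validation set: ``mstop_opt`` is the
risk-minimising iteration on the validation risk path, and the returned fit
is truncated to it by replaying the recorded coefficient updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .bivlik import BivariateCopulaModel, UnivariateModel
from .learners import BaseLearner, LearnerSpec, build_learner

__all__ = ["BoostConfig", "BoostFit", "fit_boost", "stabilize", "initialize_offsets",
           "default_learner_specs"]


@dataclass
class BoostConfig:
    step_length: float = 0.1
    mstop_max: int = 500
    stabilization: str = "L2"  # none | L2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.step_length <= 1.0):
            raise ValueError("step_length must be in (0, 1]")
        if self.mstop_max < 0:
            raise ValueError("mstop_max must be >= 0")
        if self.stabilization not in ("none", "L2"):
            raise ValueError("stabilization must be 'none' or 'L2'")


def stabilize(g, how="L2"):
    """Rescale a gradient column to unit root-mean-square (L2 stabilisation).

    A zero vector is returned unchanged; the RMS is floored at 1e-10.
    """
    if how == "none":
        return g
    rms = float(np.sqrt(np.mean(g * g)))
    if rms == 0.0:
        return g
    return g / max(rms, 1e-10)


def default_learner_specs(model, covariates, kind="linear", df=4.0, knots=20):
    """One intercept plus one learner of ``kind`` per covariate, replicated
    for every distribution parameter."""
    specs = {}
    for k in range(model.K):
        ls = [LearnerSpec("intercept")]
        for c in covariates:
            ls.append(LearnerSpec(kind, (c,), df=df, knots=knots))
        specs[k] = ls
    return specs


def initialize_offsets(model, y, eta_bounds=(-12.0, 12.0)):
    """Link-scale offsets: intercept-only maximum likelihood per margin,
    then a one-dimensional profile search for the copula predictor with the
    margins held fixed."""
    y = np.asarray(y, float)
    offsets = np.zeros(model.K)
    if isinstance(model, UnivariateModel):
        blocks = [(model, y.reshape(-1), 0)]
        ncop = 0
    else:
        blocks = [
            (UnivariateModel(model.margin1), y[:, 0], 0),
            (UnivariateModel(model.margin2), y[:, 1], model.K1),
        ]
        ncop = 1

    for uni, yj, base in blocks:
        def nll(eta_vec):
            eta = np.tile(eta_vec, (len(yj), 1))
            return uni.empirical_risk(yj, eta)

        def grad(eta_vec):
            eta = np.tile(eta_vec, (len(yj), 1))
            return -uni.gradients(yj, eta).mean(axis=0)

        res = optimize.minimize(nll, np.zeros(uni.K), jac=grad, method="BFGS")
        if not np.all(np.isfinite(res.x)):
            import warnings

            warnings.warn(f"offset optimisation failed for {uni.margin.name}; using zeros")
            res.x = np.zeros(uni.K)
        offsets[base : base + uni.K] = res.x

    if ncop:
        eta = np.tile(offsets, (len(y), 1))

        def nll_c(ec):
            e = eta.copy()
            e[:, -1] = ec
            return model.empirical_risk(y, e)

        res = optimize.minimize_scalar(nll_c, bounds=eta_bounds, method="bounded")
        offsets[-1] = float(res.x) if np.isfinite(res.x) else 0.0
    return offsets


@dataclass
class BoostFit:
    """Fitted boosting state.

    ``coef`` accumulates coefficients per (parameter, learner); ``updates``
    records every accepted update so the fit can be replayed and truncated
    to any iteration.  ``history`` is a DataFrame with the selected
    parameter/learner and the training/validation risk path.
    """

    model: object
    config: BoostConfig
    offsets: np.ndarray
    learners: dict  # param index -> list[BaseLearner]
    updates: list = field(default_factory=list)  # (param, learner_idx, coef_increment)
    history: pd.DataFrame | None = None
    mstop_opt: int = 0
    risk_offset_train: float = np.nan
    risk_offset_val: float = np.nan

    @property
    def coef(self):
        out = {
            (k, j): np.zeros(bl.n_coef)
            for k, bls in self.learners.items()
            for j, bl in enumerate(bls)
        }
        for k, j, inc in self.updates[: self.mstop_opt]:
            out[(k, j)] += inc
        return out

    def selected(self):
        """Set of (param, learner name) pairs selected up to mstop_opt."""
        return {
            (k, self.learners[k][j].spec.name) for k, j, _ in self.updates[: self.mstop_opt]
        }

    def eta(self, data: pd.DataFrame):
        n = len(data)
        eta = np.tile(self.offsets, (n, 1))
        agg = self.coef
        for (k, j), beta in agg.items():
            if np.any(beta):
                eta[:, k] += self.learners[k][j].predict(data, beta)
        return eta

    def predict(self, data: pd.DataFrame, what="params", event=None, n_samples=None, seed=0):
        """Per-observation predictions.

        what: 'eta' (additive predictors), 'params' (natural scale),
        'tau' (Kendall's tau), 'joint_prob' (requires ``event``), or
        'samples' (requires ``n_samples``).
        """
        eta = self.eta(data)
        m = self.model
        if what == "eta":
            return eta
        if what == "params":
            if isinstance(m, UnivariateModel):
                return np.column_stack(m.predictive_params(eta))
            p1, p2, th = m.natural_params(eta)
            return np.column_stack(list(p1) + list(p2) + [th])
        if what == "tau":
            return m.tau(eta)
        if what == "joint_prob":
            if event is None:
                raise ValueError("joint_prob prediction needs an event")
            return m.joint_prob(eta, event)
        if what == "samples":
            from .simulate import sample_bivariate

            if n_samples is None:
                n_samples = 1
            rng = np.random.default_rng(seed)
            return np.stack(
                [sample_bivariate(m, eta, rng) for _ in range(n_samples)], axis=1
            )
        raise ValueError(f"unknown prediction kind '{what}'")


def _response_matrix(model, data: pd.DataFrame, responses):
    if isinstance(model, UnivariateModel):
        return data[responses[0]].to_numpy(dtype=float)
    return data[list(responses)].to_numpy(dtype=float)


def fit_boost(
    model,
    train: pd.DataFrame,
    responses,
    learner_specs: dict | None = None,
    val: pd.DataFrame | None = None,
    config: BoostConfig | None = None,
    adjacency=None,
    weights=None,
):
    """Fit the boosted distributional model.

    Parameters
    ----------
    model : BivariateCopulaModel or UnivariateModel
    train, val : DataFrames holding response and covariate columns.  When
        ``val`` is None the training risk path doubles as the tuning path
        (no early stopping beyond mstop_max).
    responses : response column name(s) — a pair for bivariate models.
    learner_specs : dict param-index -> list[LearnerSpec]; defaults to
        intercept + linear learners on every non-response column.
    """
    config = config or BoostConfig()
    if isinstance(responses, str):
        responses = (responses,)
    y = _response_matrix(model, train, responses)
    y_val = _response_matrix(model, val, responses) if val is not None else None
    if learner_specs is None:
        covs = [c for c in train.columns if c not in responses]
        learner_specs = default_learner_specs(model, covs)

    learners = {
        k: [build_learner(s, train, adjacency) for s in specs]
        for k, specs in learner_specs.items()
    }
    for k in range(model.K):
        if k not in learners or not learners[k]:
            raise ValueError(f"no base-learners declared for parameter {k}")

    offsets = initialize_offsets(model, y)
    n = len(train)
    eta = np.tile(offsets, (n, 1))
    eta_val = np.tile(offsets, (len(val), 1)) if val is not None else None
    # validation designs are frozen once
    val_designs = (
        {k: [bl.design(val) for bl in bls] for k, bls in learners.items()}
        if val is not None
        else None
    )

    risk0 = model.empirical_risk(y, eta, weights)
    risk0_val = model.empirical_risk(y_val, eta_val) if val is not None else np.nan
    fit = BoostFit(model=model, config=config, offsets=offsets, learners=learners,
                   risk_offset_train=risk0, risk_offset_val=risk0_val)

    records = []
    step = config.step_length
    for m in range(1, config.mstop_max + 1):
        grads = model.gradients(y, eta)
        best = None  # (risk, k, j, coef)
        for k in range(model.K):
            u = stabilize(grads[:, k], config.stabilization)
            inner = None  # (rss, j, coef)
            for j, bl in enumerate(learners[k]):
                coef, rss = bl.fit(u)
                if inner is None or rss < inner[0] - 1e-12:
                    inner = (rss, j, coef)
            _, j, coef = inner
            trial = eta.copy()
            trial[:, k] += step * (learners[k][j].X @ coef)
            risk = model.empirical_risk(y, trial, weights)
            if np.isfinite(risk) and (best is None or risk < best[0] - 1e-12):
                best = (risk, k, j, coef)
        if best is None:
            raise RuntimeError(f"boosting aborted at iteration {m}: all candidate risks non-finite")
        risk, k, j, coef = best
        inc = step * coef
        eta[:, k] += learners[k][j].X @ inc
        fit.updates.append((k, j, inc))
        rec = {"iteration": m, "param": k, "learner": learners[k][j].spec.name,
               "risk_train": risk}
        if val is not None:
            eta_val[:, k] += val_designs[k][j] @ inc
            rec["risk_val"] = model.empirical_risk(y_val, eta_val)
        records.append(rec)

    fit.history = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["iteration", "param", "learner", "risk_train", "risk_val"]
    )
    if val is not None and config.mstop_max > 0:
        path = np.concatenate([[risk0_val], fit.history["risk_val"].to_numpy()])
        fit.mstop_opt = int(np.argmin(path))
    else:
        fit.mstop_opt = config.mstop_max
    return fit
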