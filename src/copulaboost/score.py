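"""Proper scoring rules and structure selection.

The joint negative log-likelihood and the energy score evaluate the full
predictive distribution on held-out data (lower is better for both).  The
energy score ES(F, y) = E||X - y|| - 0.5 E||X - X'|| is estimated from
Monte-Carlo draws of the fitted joint distribution; the second expectation
pairs each draw with its neighbour in the sample (X_i, X_{i+1}), which are
independent copies.  Univariate marginal metrics (Brier score and AUC for
binary margins, mean squared error of prediction otherwise) are reported
alongside, although they ignore the dependence structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bivlik import BivariateCopulaModel, UnivariateModel
from .boost import BoostConfig, fit_boost
from .simulate import sample_bivariate

__all__ = ["joint_nll", "energy_score", "energy_score_independent",
           "energy_score_from_draws", "marginal_metrics", "select_structure",
           "univariate_benchmarks", "auc"]


def _y_matrix(test, responses):
    return test[list(responses)].to_numpy(dtype=float)


def joint_nll(fit, test: pd.DataFrame, responses=("y1", "y2")):
    """Mean negative joint log-likelihood on test data at mstop_opt."""
    if isinstance(fit.model, UnivariateModel):
        y = test[responses if isinstance(responses, str) else responses[0]].to_numpy(float)
    else:
        y = _y_matrix(test, responses)
    return fit.model.empirical_risk(y, fit.eta(test))


def energy_score(fit, test: pd.DataFrame, responses=("y1", "y2"), n_samples=1000, seed=0):
    """Monte-Carlo energy score averaged over the test set.

    Draws ``n_samples`` predictive samples per observation from the fitted
    joint distribution (binary/count responses on their 0/1 and count
    scales, continuous on its natural scale).
    """
    if n_samples < 2:
        raise ValueError("energy score needs n_samples >= 2")
    y = _y_matrix(test, responses)
    eta = fit.eta(test)
    rng = np.random.default_rng(seed)
    model = fit.model
    draws = np.stack(
        [sample_bivariate(model, eta, rng) for _ in range(n_samples)], axis=1
    )  # (n, m, 2)
    return energy_score_from_draws(draws, y)


def energy_score_from_draws(draws, y):
    """Energy score from an (n, m, 2) array of predictive draws."""
    t1 = np.linalg.norm(draws - y[:, None, :], axis=2).mean(axis=1)
    t2 = np.linalg.norm(draws - np.roll(draws, 1, axis=1), axis=2).mean(axis=1)
    return float(np.mean(t1 - 0.5 * t2))


def univariate_benchmarks(model, train, val, responses=("y1", "y2"),
                          config: BoostConfig | None = None, covariates=None):
    """Fit the two margins of ``model`` as independent univariate boosted
    models, excluding *both* response columns from the covariates (so the
    benchmark cannot proxy the dependence through the other response)."""
    if covariates is None:
        covariates = [c for c in train.columns if c not in responses]
    fits = []
    for margin, resp in ((model.margin1, responses[0]), (model.margin2, responses[1])):
        from .boost import default_learner_specs

        uni = UnivariateModel(margin)
        specs = default_learner_specs(uni, covariates)
        fits.append(fit_boost(uni, train, (resp,), learner_specs=specs,
                              val=val, config=config))
    return tuple(fits)


def energy_score_independent(fit1, fit2, test, responses=("y1", "y2"),
                             n_samples=1000, seed=0):
    """Energy score of two independent univariate fits combined into a
    product predictive distribution (the no-dependence benchmark)."""
    if n_samples < 2:
        raise ValueError("energy score needs n_samples >= 2")
    y = _y_matrix(test, responses)
    rng = np.random.default_rng(seed)
    cols = []
    for fit in (fit1, fit2):
        eta = fit.eta(test)
        margin = fit.model.margin
        params = margin.params_from_eta([eta[:, k] for k in range(fit.model.K)])
        q = rng.uniform(size=(len(test), n_samples))
        col = np.stack(
            [margin.quantile(q[:, m], params) for m in range(n_samples)], axis=1
        )
        cols.append(col)
    draws = np.stack([cols[0], cols[1]], axis=2)  # (n, m, 2)
    return energy_score_from_draws(draws, y)


def auc(score, labels):
    """Area under the ROC curve via the Mann-Whitney rank statistic;
    NaN when the labels are constant."""
    labels = np.asarray(labels, float)
    score = np.asarray(score, float)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(score)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def marginal_metrics(fit, test: pd.DataFrame, responses=("y1", "y2")):
    """Per-margin metrics: Brier score and AUC for binary margins, mean
    squared error of prediction (predictive mean) otherwise."""
    model = fit.model
    eta = fit.eta(test)
    p1, p2, _ = model.natural_params(eta)
    out = {}
    for j, (margin, params) in enumerate([(model.margin1, p1), (model.margin2, p2)], start=1):
        y = test[responses[j - 1]].to_numpy(float)
        if margin.support == "binary":
            phat = params[0]
            out[f"brier{j}"] = float(np.mean((phat - y) ** 2))
            out[f"auc{j}"] = auc(phat, y)
        else:
            yhat = margin.mean(params)
            out[f"msep{j}"] = float(np.mean((y - yhat) ** 2))
    return out


def select_structure(
    candidates,
    train,
    val,
    test,
    responses=("y1", "y2"),
    learner_specs=None,
    config: BoostConfig | None = None,
    adjacency=None,
):
    """Fit candidate model structures and rank them by out-of-sample NLL.

    ``candidates`` is a dict name -> BivariateCopulaModel (or a list of
    models, keyed by their copula name).  Each candidate is tuned on its own
    validation-risk path.  Returns (ranking DataFrame, winner name, fits).
    """
    if not isinstance(candidates, dict):
        candidates = {
            f"{m.copula.name}{m.copula.rotation or ''}": m for m in candidates
        }
    rows, fits = [], {}
    for name, model in candidates.items():
        try:
            fit = fit_boost(model, train, responses, learner_specs=learner_specs,
                            val=val, config=config, adjacency=adjacency)
            nll = joint_nll(fit, test, responses)
            rows.append({"candidate": name, "test_nll": nll, "mstop_opt": fit.mstop_opt})
            fits[name] = fit
        except Exception as exc:  # a failed candidate is excluded, not fatal
            rows.append({"candidate": name, "test_nll": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("test_nll").reset_index(drop=True)
    winner = table.loc[0, "candidate"] if np.isfinite(table.loc[0, "test_nll"]) else None
    return table, winner, fits
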