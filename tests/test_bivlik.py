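"""Joint likelihoods: normalization, independence reduction, analytic
score vectors vs finite differences, joint probabilities.
"""

import numpy as np
import pytest

from copulaboost.bivlik import BivariateCopulaModel, UnivariateModel, infer_response_kind
from copulaboost.copulas import get_copula
from copulaboost.margins import get_margin
from copulaboost.simulate import sample_bivariate

from conftest import ALL_FAMILIES


def _model(kind, copname="clayton"):
    cop = get_copula(copname)
    if kind == "binary":
        return BivariateCopulaModel(get_margin("bernoulli"), get_margin("bernoulli"), cop)
    if kind == "count":
        return BivariateCopulaModel(get_margin("poisson"), get_margin("poisson"), cop)
    if kind == "mixed":
        return BivariateCopulaModel(get_margin("bernoulli"), get_margin("gaussian_hetero"), cop)
    raise ValueError(kind)


def _eta(model, rng, n, scale=0.6):
    return rng.normal(0.0, scale, size=(n, model.K))


def test_response_kind_inference():
    assert infer_response_kind(get_margin("bernoulli"), get_margin("bernoulli")) == "binary_binary"
    assert infer_response_kind(get_margin("poisson"), get_margin("nbinom1")) == "count_count"
    assert (
        infer_response_kind(get_margin("bernoulli"), get_margin("gaussian_hetero"))
        == "binary_continuous"
    )
    with pytest.raises(ValueError):
        infer_response_kind(get_margin("gaussian_hetero"), get_margin("bernoulli"))


def test_binary_cells_sum_to_one(rng):
    model = _model("binary")
    eta = _eta(model, rng, 200)
    p1, p2, th = model.natural_params(eta)
    total = np.zeros(200)
    for y1 in (0.0, 1.0):
        for y2 in (0.0, 1.0):
            y = np.column_stack([np.full(200, y1), np.full(200, y2)])
            total += np.exp(model.loglik(y, eta))
    np.testing.assert_allclose(total, 1.0, atol=1e-12)


def test_count_rectangle_sums_to_one(rng):
    model = _model("count")
    eta = _eta(model, rng, 5, scale=0.4)
    grid = np.arange(0, 60)
    total = np.zeros(5)
    for y1 in grid:
        Y = np.column_stack([np.full(grid.size, float(y1)), grid.astype(float)])
        for i in range(5):
            total[i] += np.exp(model.loglik(Y, np.tile(eta[i], (grid.size, 1)))).sum()
    np.testing.assert_allclose(total, 1.0, atol=1e-6)


def test_mixed_density_normalizes(rng):
    from scipy import integrate

    model = _model("mixed")
    eta = np.array([[0.3, 0.2, 0.5, 0.4]])
    total = 0.0
    for y1 in (0.0, 1.0):
        val, _ = integrate.quad(
            lambda y2: float(np.exp(model.loglik(np.array([[y1, y2]]), eta))[0]),
            -12, 12, epsabs=1e-9,
        )
        total += val
    assert total == pytest.approx(1.0, abs=1e-7)


@pytest.mark.parametrize("kind", ["binary", "count", "mixed"])
def test_independence_reduces_to_univariate_sum(kind, rng):
    """With the dependence parameter at its independence point, the joint
    log-likelihood equals the sum of marginal log-likelihoods."""
    model = _model(kind, "frank")  # frank: theta=0 <-> independence
    n = 100
    eta = _eta(model, rng, n)
    eta[:, -1] = 0.0
    y = sample_bivariate(model, eta, rng)
    joint = model.loglik(y, eta)
    u1 = UnivariateModel(model.margin1)
    u2 = UnivariateModel(model.margin2)
    sep = u1.loglik(y[:, 0], eta[:, : model.K1]) + u2.loglik(y[:, 1], eta[:, model.K1 : -1])
    np.testing.assert_allclose(joint, sep, atol=1e-10)


@pytest.mark.parametrize("kind", ["binary", "count", "mixed"])
@pytest.mark.parametrize("cop", ALL_FAMILIES + ["clayton270"])
def test_analytic_score_vs_fd(kind, cop, rng):
    """Analytic gradients match central finite differences at responses
    drawn from the model itself (so no likelihood cell is saturated)."""
    model = _model(kind, cop)
    n = 40
    eta = _eta(model, rng, n, scale=0.5)
    y = sample_bivariate(model, eta, rng)
    g = model.gradients(y, eta)
    gf = model.gradients(y, eta, method="fd")
    np.testing.assert_allclose(g, gf, rtol=2e-4, atol=2e-5)


def test_empirical_risk_is_mean_negative_loglik(rng):
    model = _model("count")
    eta = _eta(model, rng, 50)
    y = sample_bivariate(model, eta, rng)
    assert model.empirical_risk(y, eta) == pytest.approx(-np.mean(model.loglik(y, eta)))
    w = rng.uniform(0.5, 2.0, 50)
    ref = -np.sum(w * model.loglik(y, eta)) / np.sum(w)
    assert model.empirical_risk(y, eta, w) == pytest.approx(ref)


def test_tau_and_param_split(rng):
    model = _model("mixed", "clayton")
    eta = _eta(model, rng, 10)
    assert model.K == model.K1 + model.K2 + 1 == 4
    t = model.tau(eta)
    th = model.copula.theta_from_eta(eta[:, -1])
    np.testing.assert_allclose(t, th / (th + 2.0), rtol=1e-12)


def test_joint_prob_binary_event(rng):
    model = _model("binary", "gumbel")
    eta = _eta(model, rng, 30)
    p11 = model.joint_prob(eta, (1, 1))
    p1, p2, th = model.natural_params(eta)
    np.testing.assert_allclose(p11, model.copula.cdf(p1[0], p2[0], th), atol=1e-12)
    # all four cells sum to one
    total = sum(model.joint_prob(eta, (a, b)) for a in (0, 1) for b in (0, 1))
    np.testing.assert_allclose(total, 1.0, atol=1e-10)


def test_joint_prob_count_interval(rng):
    """P(Y1 <= a, Y2 <= b) from joint_prob equals the copula of the margins."""
    model = _model("count", "clayton")
    eta = _eta(model, rng, 20, scale=0.4)
    p = model.joint_prob(eta, (("le", 3), ("le", 2)))
    p1, p2, th = model.natural_params(eta)
    F1 = model.margin1.cdf(np.full(20, 3.0), p1)
    F2 = model.margin2.cdf(np.full(20, 2.0), p2)
    np.testing.assert_allclose(p, model.copula.cdf(F1, F2, th), atol=1e-12)


def test_validate_shape_and_values():
    model = _model("binary")
    with pytest.raises(ValueError):
        model.validate(np.zeros((5, 3)))
    with pytest.raises(ValueError):
        model.validate(np.array([[0.0, 2.0]]))


def test_string_construction():
    m = BivariateCopulaModel("poisson", "poisson", "clayton")
    assert m.response_kind == "count_count" and m.copula.name == "clayton"
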