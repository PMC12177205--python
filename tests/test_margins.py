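"""Marginal families: pmf/pdf correctness against scipy, normalization,
derivatives vs finite differences, CDF consistency, generalized inverses.
"""

import numpy as np
import pytest
from scipy import stats

from copulaboost.margins import get_margin

ALL_MARGINS = [
    "bernoulli", "gaussian_hetero", "poisson", "geometric", "nbinom1",
    "zip", "zinb", "zalogarithmic", "zanbinom",
]

# moderate natural-scale parameter values per family (one column per parameter)
PARAMS = {
    "bernoulli": [0.35],
    "gaussian_hetero": [0.4, 1.3],
    "poisson": [2.5],
    "geometric": [1.8],
    "nbinom1": [2.5, 0.7],
    "zip": [2.5, 0.25],
    "zinb": [2.5, 0.7, 0.25],
    "zalogarithmic": [0.6, 0.3],
    "zanbinom": [2.5, 0.7, 0.3],
}


def _params(name, n=1):
    return [np.full(n, v) for v in PARAMS[name]]


def _grid(name, n=1):
    if name == "bernoulli":
        return np.array([0.0, 1.0])
    return np.arange(0.0, 400.0)


# ---------------------------------------------------------------------------
# exact pmf values against scipy / closed forms
# ---------------------------------------------------------------------------


def test_poisson_matches_scipy():
    m = get_margin("poisson")
    y = np.array([0.0, 1.0, 3.0, 7.0])
    got = m.pdf(y, [np.full(4, 2.5)])
    np.testing.assert_allclose(got, stats.poisson.pmf(y, 2.5), rtol=1e-12)


def test_geometric_mean_parameterisation():
    """f(y) = mu^y / (1 + mu)^(y + 1): a geometric on {0,1,...} with mean mu."""
    m = get_margin("geometric")
    mu = 1.8
    y = np.array([0.0, 1.0, 4.0])
    np.testing.assert_allclose(
        m.pdf(y, [np.full(3, mu)]), mu**y / (1 + mu) ** (y + 1), rtol=1e-12
    )
    # equivalently scipy's geom with p = 1/(1+mu), support shifted to 0
    np.testing.assert_allclose(
        m.pdf(y, [np.full(3, mu)]), stats.geom.pmf(y + 1, 1 / (1 + mu)), rtol=1e-12
    )
    assert m.mean([np.array([mu])])[0] == pytest.approx(mu)


def test_nbinom1_matches_scipy():
    """Type-I negative binomial: mean mu, variance mu (1 + sigma mu)."""
    m = get_margin("nbinom1")
    mu, sig = 2.5, 0.7
    r = 1.0 / sig
    p = r / (r + mu)
    y = np.array([0.0, 2.0, 5.0])
    np.testing.assert_allclose(
        m.pdf(y, [np.full(3, mu), np.full(3, sig)]), stats.nbinom.pmf(y, r, p), rtol=1e-10
    )
    grid = np.arange(4000.0)
    f = m.pdf(grid, [np.full(grid.size, mu), np.full(grid.size, sig)])
    var = float(np.sum(f * grid**2) - np.sum(f * grid) ** 2)
    assert var == pytest.approx(mu * (1 + sig * mu), rel=1e-8)


def test_zero_inflated_and_hurdle_zero_probabilities():
    y0 = np.array([0.0])
    zip_ = get_margin("zip")
    assert zip_.pdf(y0, [np.array([2.5]), np.array([0.25])])[0] == pytest.approx(
        0.25 + 0.75 * np.exp(-2.5), rel=1e-12
    )
    zal = get_margin("zalogarithmic")
    assert zal.pdf(y0, [np.array([0.6]), np.array([0.3])])[0] == pytest.approx(0.3)
    zan = get_margin("zanbinom")
    assert zan.pdf(y0, [np.array([2.5]), np.array([0.7]), np.array([0.3])])[0] == pytest.approx(0.3)


def test_zalogarithmic_series_pmf():
    """Above zero: (1 - pi0) times the logarithmic pmf -p^y / (y log(1-p))."""
    m = get_margin("zalogarithmic")
    p, pi0 = 0.6, 0.3
    y = np.array([1.0, 2.0, 5.0])
    ref = (1 - pi0) * (-(p**y) / (y * np.log1p(-p)))
    np.testing.assert_allclose(m.pdf(y, [np.full(3, p), np.full(3, pi0)]), ref, rtol=1e-12)
    np.testing.assert_allclose(
        m.pdf(y, [np.full(3, p), np.full(3, pi0)]) / (1 - pi0),
        stats.logser.pmf(y, p),
        rtol=1e-10,
    )


def test_zanbinom_is_hurdle():
    """Above zero: (1 - pi0) times the zero-truncated NB pmf."""
    m = get_margin("zanbinom")
    mu, sig, pi0 = 2.5, 0.7, 0.3
    r, p = 1 / sig, (1 / sig) / (1 / sig + mu)
    y = np.array([1.0, 3.0])
    ref = (1 - pi0) * stats.nbinom.pmf(y, r, p) / (1 - stats.nbinom.pmf(0, r, p))
    np.testing.assert_allclose(
        m.pdf(y, [np.full(2, mu), np.full(2, sig), np.full(2, pi0)]), ref, rtol=1e-10
    )


def test_gaussian_hetero_matches_scipy():
    m = get_margin("gaussian_hetero")
    y = np.array([-1.0, 0.3, 2.0])
    mu, sig = np.full(3, 0.4), np.full(3, 1.3)
    np.testing.assert_allclose(m.logpdf(y, [mu, sig]), stats.norm.logpdf(y, 0.4, 1.3), rtol=1e-12)
    np.testing.assert_allclose(m.cdf(y, [mu, sig]), stats.norm.cdf(y, 0.4, 1.3), rtol=1e-12)


# ---------------------------------------------------------------------------
# generic properties for every family
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("name", [m for m in ALL_MARGINS if m != "gaussian_hetero"])
def test_pmf_normalizes(name):
    m = get_margin(name)
    grid = _grid(name)
    f = m.pdf(grid, _params(name, grid.size))
    assert f.sum() == pytest.approx(1.0, abs=1e-8)
    assert np.all(f >= 0)


@pytest.mark.parametrize("name", [m for m in ALL_MARGINS if m != "gaussian_hetero"])
def test_cdf_is_cumulative_pmf(name):
    m = get_margin(name)
    grid = _grid(name)[:30]
    f = m.pdf(grid, _params(name, grid.size))
    F = m.cdf(grid, _params(name, grid.size))
    np.testing.assert_allclose(F, np.cumsum(f), rtol=1e-10, atol=1e-14)


@pytest.mark.parametrize("name", ALL_MARGINS)
def test_dlogpdf_vs_fd(name, rng):
    m = get_margin(name)
    n = 40
    params = _params(name, n)
    if name == "gaussian_hetero":
        y = rng.normal(0.4, 1.3, n)
    elif name == "bernoulli":
        y = (rng.uniform(size=n) < 0.35).astype(float)
    elif name == "zalogarithmic":
        y = rng.integers(0, 6, n).astype(float)
    else:
        y = rng.integers(0, 8, n).astype(float)
    eps = 1e-6
    for k in range(m.n_params):
        hi = [p.copy() for p in params]
        lo = [p.copy() for p in params]
        hi[k] = hi[k] + eps
        lo[k] = lo[k] - eps
        fd = (m.logpdf(y, hi) - m.logpdf(y, lo)) / (2 * eps)
        np.testing.assert_allclose(m.dlogpdf(y, params, k), fd, rtol=5e-5, atol=1e-6)


@pytest.mark.parametrize("name", ALL_MARGINS)
def test_dcdf_vs_fd(name, rng):
    m = get_margin(name)
    n = 30
    params = _params(name, n)
    if name == "gaussian_hetero":
        y = rng.normal(0.4, 1.3, n)
    elif name == "bernoulli":
        y = np.zeros(n)
    else:
        y = rng.integers(0, 8, n).astype(float)
    eps = 1e-6
    for k in range(m.n_params):
        hi = [p.copy() for p in params]
        lo = [p.copy() for p in params]
        hi[k] = hi[k] + eps
        lo[k] = lo[k] - eps
        fd = (m.cdf(y, hi) - m.cdf(y, lo)) / (2 * eps)
        np.testing.assert_allclose(m.dcdf(y, params, k), fd, rtol=5e-5, atol=1e-6)


@pytest.mark.parametrize("name", [m for m in ALL_MARGINS if m != "gaussian_hetero"])
def test_quantile_is_generalized_inverse(name, rng):
    """F(Q(q) - 1) < q <= F(Q(q)) for discrete margins."""
    m = get_margin(name)
    q = rng.uniform(0.01, 0.99, 50)
    params = _params(name, 50)
    y = m.quantile(q, params)
    F_at = m.cdf(y, params)
    assert np.all(F_at >= q - 1e-12)
    below = y > 0
    if below.any():
        F_prev = m.cdf(y[below] - 1, [p[below] for p in params])
        assert np.all(F_prev < q[below])


def test_quantile_continuous():
    m = get_margin("gaussian_hetero")
    q = np.array([0.1, 0.5, 0.9])
    y = m.quantile(q, [np.full(3, 0.4), np.full(3, 1.3)])
    np.testing.assert_allclose(y, stats.norm.ppf(q, 0.4, 1.3), rtol=1e-10)


@pytest.mark.parametrize("name", ALL_MARGINS)
def test_params_from_eta_within_domain(name, rng):
    m = get_margin(name)
    eta = [rng.uniform(-3, 3, 50) for _ in range(m.n_params)]
    params = m.params_from_eta(eta)
    y = np.zeros(50) if m.support != "continuous" else rng.normal(size=50)
    assert np.all(np.isfinite(m.logpdf(y, params)))
    # chain-rule factors match finite differences of the inverse links
    eps = 1e-6
    d = m.dparams_deta(eta)
    for k in range(m.n_params):
        hi = [e.copy() for e in eta]
        lo = [e.copy() for e in eta]
        hi[k] += eps
        lo[k] -= eps
        fd = (m.params_from_eta(hi)[k] - m.params_from_eta(lo)[k]) / (2 * eps)
        np.testing.assert_allclose(d[k], fd, rtol=1e-5, atol=1e-8)


def test_bernoulli_links():
    for link in ("logit", "probit", "cloglog"):
        m = get_margin("bernoulli", link=link)
        eta = np.array([-1.0, 0.0, 2.0])
        p = m.params_from_eta([eta])[0]
        assert np.all((p > 0) & (p < 1))
    p = get_margin("bernoulli", link="probit").params_from_eta([np.array([0.7])])[0]
    assert p[0] == pytest.approx(stats.norm.cdf(0.7), rel=1e-12)


def test_validation_rejects_bad_responses():
    with pytest.raises(ValueError):
        get_margin("bernoulli").validate(np.array([0.0, 2.0]))
    with pytest.raises(ValueError):
        get_margin("poisson").validate(np.array([1.5]))
    with pytest.raises(ValueError):
        get_margin("poisson").validate(np.array([-1.0]))
    with pytest.raises(ValueError):
        get_margin("nosuchmargin")
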