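"""Copula CDFs, h-functions, densities, dependence derivatives, rotations.

Oracles: closed-form CDF expressions written out independently here, the
bivariate-normal CDF from scipy, and central finite differences.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from copulaboost.copulas import get_copula

from conftest import ALL_FAMILIES, ROTATIONS, random_theta

UV = (0.3, 0.7)


# frozen closed-form oracle values at (u, v) = (0.3, 0.7)
ORACLE_CDF = {
    ("clayton", 2.5): 0.2918864840923416,
    ("gumbel", 2.0): 0.2848780620209499,
    ("frank", 4.0): 0.2760744063930273,
    ("gaussian", 0.5): 0.2669038488673631,
    ("fgm", 0.5): 0.23204999999999998,
    ("amh", 0.5): 0.23463687150837986,
}


@pytest.mark.parametrize("key", sorted(ORACLE_CDF))
def test_cdf_against_closed_forms(key):
    name, theta = key
    cop = get_copula(name)
    got = cop.cdf(np.array([UV[0]]), np.array([UV[1]]), np.array([theta]))[0]
    assert got == pytest.approx(ORACLE_CDF[key], rel=1e-9, abs=1e-12)


def test_gaussian_cdf_vs_scipy(rng):
    cop = get_copula("gaussian")
    for _ in range(20):
        u, v = rng.uniform(0.05, 0.95, 2)
        r = rng.uniform(-0.9, 0.9)
        x, y = stats.norm.ppf([u, v])
        ref = stats.multivariate_normal(cov=[[1.0, r], [r, 1.0]]).cdf([x, y])
        got = cop.cdf(np.array([u]), np.array([v]), np.array([r]))[0]
        assert got == pytest.approx(ref, abs=5e-10)


def test_rotation_identities(rng):
    """Rotated CDFs follow the survival-transform identities of the base."""
    base = get_copula("clayton")
    u, v = rng.uniform(0.05, 0.95, 50), rng.uniform(0.05, 0.95, 50)
    t = random_theta("clayton", rng, 50)
    C = lambda a, b: base.cdf(a, b, t)
    np.testing.assert_allclose(get_copula("clayton90").cdf(u, v, t), v - C(1 - u, v), atol=1e-12)
    np.testing.assert_allclose(
        get_copula("clayton180").cdf(u, v, t), u + v - 1 + C(1 - u, 1 - v), atol=1e-12
    )
    np.testing.assert_allclose(get_copula("clayton270").cdf(u, v, t), u - C(u, 1 - v), atol=1e-12)


@pytest.mark.parametrize("name", ALL_FAMILIES + ROTATIONS)
def test_frechet_bounds_and_margins(name, rng):
    cop = get_copula(name)
    n = 200
    u, v = rng.uniform(0.01, 0.99, n), rng.uniform(0.01, 0.99, n)
    t = random_theta(name, rng, n)
    c = cop.cdf(u, v, t)
    lower = np.maximum(u + v - 1.0, 0.0)
    upper = np.minimum(u, v)
    assert np.all(c >= lower - 1e-10) and np.all(c <= upper + 1e-10)
    ones = np.ones(n)
    np.testing.assert_allclose(cop.cdf(u, ones, t), u, atol=1e-9)
    np.testing.assert_allclose(cop.cdf(ones, v, t), v, atol=1e-9)
    # inputs are floored at 1e-12 before evaluation, so C(0, v) <= that floor
    np.testing.assert_allclose(cop.cdf(np.zeros(n), v, t), 0.0, atol=1e-11)


@pytest.mark.parametrize("name", ALL_FAMILIES + ROTATIONS)
def test_two_increasing(name, rng):
    cop = get_copula(name)
    n = 100
    u1 = rng.uniform(0.01, 0.9, n)
    v1 = rng.uniform(0.01, 0.9, n)
    u2 = u1 + rng.uniform(0.01, 0.99 - u1.max(), n).clip(0.005)
    v2 = v1 + rng.uniform(0.01, 0.99 - v1.max(), n).clip(0.005)
    t = random_theta(name, rng, n)
    vol = cop.cdf(u2, v2, t) - cop.cdf(u1, v2, t) - cop.cdf(u2, v1, t) + cop.cdf(u1, v1, t)
    assert np.all(vol >= -1e-11)


@pytest.mark.parametrize("name", ALL_FAMILIES + ROTATIONS)
def test_hfun_and_dtheta_vs_fd(name, rng):
    cop = get_copula(name)
    n = 100
    u, v = rng.uniform(0.05, 0.95, n), rng.uniform(0.05, 0.95, n)
    t = random_theta(name, rng, n)
    eps = 1e-6

    hu = cop.hfun(u, v, t, wrt="u")
    fd = (cop.cdf(u + eps, v, t) - cop.cdf(u - eps, v, t)) / (2 * eps)
    np.testing.assert_allclose(hu, fd, rtol=1e-5, atol=1e-7)

    hv = cop.hfun(u, v, t, wrt="v")
    fd = (cop.cdf(u, v + eps, t) - cop.cdf(u, v - eps, t)) / (2 * eps)
    np.testing.assert_allclose(hv, fd, rtol=1e-5, atol=1e-7)

    et = eps * np.maximum(1.0, np.abs(t))
    dt = cop.dtheta(u, v, t)
    fd = (cop.cdf(u, v, t + et) - cop.cdf(u, v, t - et)) / (2 * et)
    np.testing.assert_allclose(dt, fd, rtol=1e-5, atol=1e-7)


@pytest.mark.parametrize("name", ALL_FAMILIES + ROTATIONS)
def test_density_integrates_to_one(name, rng):
    cop = get_copula(name)
    theta = float(random_theta(name, rng, 1)[0])
    val, _ = integrate.dblquad(
        lambda y, x: float(cop.density(np.array([x]), np.array([y]), np.array([theta]))[0]),
        1e-6, 1 - 1e-6, 1e-6, 1 - 1e-6, epsabs=1e-6, epsrel=1e-6,
    )
    assert val == pytest.approx(1.0, abs=1e-3)


@pytest.mark.parametrize("name", ALL_FAMILIES + ROTATIONS)
def test_hv_block_partials_vs_fd(name, rng):
    """The mixed-likelihood block: h_v plus its partials in u, v, theta."""
    cop = get_copula(name)
    n = 60
    u, v = rng.uniform(0.1, 0.9, n), rng.uniform(0.1, 0.9, n)
    t = random_theta(name, rng, n)
    eps = 1e-6
    hv, dhu, dhv, dht = cop.hv_block(u, v, t)
    np.testing.assert_allclose(hv, cop.hfun(u, v, t, wrt="v"), atol=1e-12)
    fd = (cop.hfun(u + eps, v, t, wrt="v") - cop.hfun(u - eps, v, t, wrt="v")) / (2 * eps)
    np.testing.assert_allclose(dhu, fd, rtol=2e-5, atol=1e-6)
    fd = (cop.hfun(u, v + eps, t, wrt="v") - cop.hfun(u, v - eps, t, wrt="v")) / (2 * eps)
    np.testing.assert_allclose(dhv, fd, rtol=2e-5, atol=1e-6)
    et = eps * np.maximum(1.0, np.abs(t))
    fd = (cop.hfun(u, v, t + et, wrt="v") - cop.hfun(u, v, t - et, wrt="v")) / (2 * et)
    np.testing.assert_allclose(dht, fd, rtol=2e-5, atol=1e-6)


def test_dhu_is_density(rng):
    """d h_v / d u is the copula density."""
    for name in ALL_FAMILIES:
        cop = get_copula(name)
        u, v = rng.uniform(0.1, 0.9, 20), rng.uniform(0.1, 0.9, 20)
        t = random_theta(name, rng, 20)
        _, dhu, _, _ = cop.hv_block(u, v, t)
        np.testing.assert_allclose(dhu, cop.density(u, v, t), rtol=1e-8, atol=1e-10)


def test_tau_closed_forms():
    assert get_copula("clayton").tau(np.array([2.0]))[0] == pytest.approx(0.5)
    assert get_copula("gumbel").tau(np.array([2.0]))[0] == pytest.approx(0.5)
    assert get_copula("gaussian").tau(np.array([0.5]))[0] == pytest.approx(
        2 / np.pi * np.arcsin(0.5)
    )
    assert get_copula("fgm").tau(np.array([0.5]))[0] == pytest.approx(1 / 9)
    assert get_copula("frank").tau(np.array([4.0]))[0] == pytest.approx(
        0.3881480212979379, abs=1e-9
    )
    assert get_copula("amh").tau(np.array([0.5]))[0] == pytest.approx(
        0.12876478703996364, abs=1e-9
    )
    # rotations by 90/270 flip the sign of tau
    assert get_copula("clayton90").tau(np.array([2.0]))[0] == pytest.approx(-0.5)
    assert get_copula("clayton270").tau(np.array([2.0]))[0] == pytest.approx(-0.5)
    assert get_copula("clayton180").tau(np.array([2.0]))[0] == pytest.approx(0.5)


def test_independence_limits():
    u = np.array([0.3, 0.6])
    v = np.array([0.8, 0.2])
    for name, t0 in [("gaussian", 0.0), ("clayton", 1e-9), ("gumbel", 1.0),
                     ("frank", 0.0), ("fgm", 0.0), ("amh", 0.0)]:
        cop = get_copula(name)
        t = np.full(2, t0)
        np.testing.assert_allclose(cop.cdf(u, v, t), u * v, atol=1e-8, err_msg=name)
        np.testing.assert_allclose(cop.density(u, v, t), 1.0, atol=1e-6, err_msg=name)


def test_link_and_eta_mapping(rng):
    """theta_from_eta respects the family's admissible range and the
    chain-rule factor matches finite differences."""
    for name in ALL_FAMILIES:
        cop = get_copula(name)
        eta = rng.uniform(-3, 3, 50)
        t = cop.theta_from_eta(eta)
        lo, hi = cop.theta_box
        assert np.all(t >= lo - 1e-12) and np.all(t <= hi + 1e-12)
        eps = 1e-6
        fd = (cop.theta_from_eta(eta + eps) - cop.theta_from_eta(eta - eps)) / (2 * eps)
        np.testing.assert_allclose(cop.dtheta_deta(eta), fd, rtol=1e-5, atol=1e-7)


@given(
    u=st.floats(0.001, 0.999),
    v=st.floats(0.001, 0.999),
    x=st.floats(-0.999, 0.999),
)
def test_property_bounds_and_hfun_range(u, v, x):
    """For any admissible point: Fréchet bounds hold and the h-function is a
    valid conditional CDF value, in every family."""
    for name in ALL_FAMILIES:
        cop = get_copula(name)
        lo, hi = cop.theta_box
        theta = lo + (np.tanh(3 * x) * 0.5 + 0.5) * (min(hi, 30.0) - lo)
        if name == "gumbel":
            theta = max(theta, 1.0)
        ua, va, ta = np.array([u]), np.array([v]), np.array([theta])
        c = cop.cdf(ua, va, ta)[0]
        assert max(u + v - 1, 0) - 1e-9 <= c <= min(u, v) + 1e-9, name
        h = cop.hfun(ua, va, ta, wrt="u")[0]
        assert -1e-9 <= h <= 1 + 1e-9, name


def test_invalid_theta_rejected():
    cop = get_copula("clayton")
    with pytest.raises(ValueError):
        cop.cdf(np.array([0.5]), np.array([0.5]), np.array([-1.0]))
    with pytest.raises(ValueError):
        get_copula("gumbel").cdf(np.array([0.5]), np.array([0.5]), np.array([0.5]))
    with pytest.raises(ValueError):
        get_copula("nosuch")
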