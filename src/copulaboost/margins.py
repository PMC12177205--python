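"""Parametric marginal distribution families.

Families cover the three response supports of the bivariate models:

* binary      -- Bernoulli (logit/probit/cloglog link);
* continuous  -- heteroscedastic Gaussian (identity/log links);
* count       -- Poisson, Geometric, negative binomial type I
                 (variance mu(1 + sigma*mu)), zero-inflated Poisson and
                 negative binomial, and zero-altered (hurdle) logarithmic
                 and negative binomial.

Every family provides the (log-)density or mass, the CDF, the generalized
inverse quantile, the predictive mean, and analytic derivatives of log f and
F with respect to each distribution parameter.  Discrete CDFs are computed
by explicit summation of the pmf over 0..y, so that the identity
F(y) - f(y) = F(y-1) used by the discrete copula likelihood holds exactly;
dF/dparam follows by summing f * dlogf/dparam over the same grid.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

from .links import IdentityLink, Link, LogLink, get_link

__all__ = ["Margin", "get_margin", "MARGIN_FAMILIES"]


class Margin:
    name: str = "abstract"
    support: str = "count"  # binary | count | continuous
    n_params: int = 1
    param_names: tuple = ("mu",)

    def __init__(self, links=None):
        self.links: list[Link] = list(links) if links is not None else self._default_links()
        if len(self.links) != self.n_params:
            raise ValueError(f"{self.name} needs {self.n_params} links")

    def _default_links(self):
        raise NotImplementedError

    # -- densities ----------------------------------------------------------
    def logpdf(self, y, params):
        raise NotImplementedError

    def pdf(self, y, params):
        return np.exp(self.logpdf(y, params))

    def dlogpdf(self, y, params, k):
        """d log f(y) / d theta_k on the natural parameter scale."""
        raise NotImplementedError

    # -- CDF and its parameter derivatives -----------------------------------
    def cdf(self, y, params):
        raise NotImplementedError

    def dcdf(self, y, params, k):
        """d F(y) / d theta_k."""
        raise NotImplementedError

    def quantile(self, q, params):
        """Generalized inverse: smallest y in the support with F(y) >= q."""
        raise NotImplementedError

    def mean(self, params):
        raise NotImplementedError

    # -- link-scale helpers ---------------------------------------------------
    def params_from_eta(self, eta_cols):
        """Map link-scale predictor columns to natural-scale parameters."""
        return [lk.inverse(e) for lk, e in zip(self.links, eta_cols)]

    def dparams_deta(self, eta_cols):
        return [lk.deriv(e) for lk, e in zip(self.links, eta_cols)]

    def validate(self, y):
        y = np.asarray(y)
        if self.support == "binary":
            if not np.isin(y, (0, 1)).all():
                raise ValueError(f"binary margin '{self.name}': responses must be in {{0,1}}")
        elif self.support == "count":
            if np.any(y < 0) or not np.allclose(y, np.round(y)):
                raise ValueError(
                    f"count margin '{self.name}': responses must be non-negative integers"
                )
        return np.asarray(y, float)

    def __repr__(self):  # pragma: no cover
        return f"<margin {self.name}>"


# ---------------------------------------------------------------------------
# Binary
# ---------------------------------------------------------------------------


class Bernoulli(Margin):
    name = "bernoulli"
    support = "binary"
    n_params = 1
    param_names = ("p",)

    def __init__(self, links=None, link="logit"):
        if links is None:
            links = [get_link(link)]
        super().__init__(links)

    def _default_links(self):
        return [get_link("logit")]

    def logpdf(self, y, params):
        (p,) = params
        y = np.asarray(y, float)
        return y * np.log(p) + (1 - y) * np.log1p(-p)

    def dlogpdf(self, y, params, k):
        (p,) = params
        y = np.asarray(y, float)
        return y / p - (1 - y) / (1 - p)

    def cdf(self, y, params):
        (p,) = params
        y = np.asarray(y, float)
        return np.where(y < 0, 0.0, np.where(y < 1, 1.0 - p, 1.0))

    def dcdf(self, y, params, k):
        (p,) = params
        y = np.asarray(y, float)
        return np.where((y >= 0) & (y < 1), -np.ones_like(p * y), 0.0)

    def quantile(self, q, params):
        (p,) = params
        return (np.asarray(q, float) > 1.0 - p).astype(float)

    def mean(self, params):
        return params[0]


# ---------------------------------------------------------------------------
# Continuous
# ---------------------------------------------------------------------------


class GaussianHetero(Margin):
    """Gaussian with covariate-dependent mean (identity link) and standard
    deviation (log link)."""

    name = "gaussian_hetero"
    support = "continuous"
    n_params = 2
    param_names = ("mu", "sigma")

    def _default_links(self):
        return [IdentityLink(), LogLink(hi=1e6)]

    def logpdf(self, y, params):
        mu, sg = params
        z = (np.asarray(y, float) - mu) / sg
        return -0.5 * z * z - np.log(sg) - 0.5 * np.log(2 * np.pi)

    def dlogpdf(self, y, params, k):
        mu, sg = params
        z = (np.asarray(y, float) - mu) / sg
        if k == 0:
            return z / sg
        return (z * z - 1.0) / sg

    def cdf(self, y, params):
        mu, sg = params
        return stats.norm.cdf(np.asarray(y, float), loc=mu, scale=sg)

    def dcdf(self, y, params, k):
        mu, sg = params
        z = (np.asarray(y, float) - mu) / sg
        phi = stats.norm.pdf(z)
        if k == 0:
            return -phi / sg
        return -phi * z / sg

    def quantile(self, q, params):
        mu, sg = params
        return stats.norm.ppf(np.asarray(q, float), loc=mu, scale=sg)

    def mean(self, params):
        return params[0]


# ---------------------------------------------------------------------------
# Counts: generic machinery
# ---------------------------------------------------------------------------


class CountMargin(Margin):
    support = "count"
    _tail = 1e-12  # truncation tail mass for quantile scans

    def logpmf(self, y, params):
        """Vectorised log pmf; y broadcastable against the parameter arrays."""
        raise NotImplementedError

    def dlogpmf(self, y, params, k):
        raise NotImplementedError

    # Margin interface in terms of the pmf grid ------------------------------
    def logpdf(self, y, params):
        return self.logpmf(np.asarray(y, float), params)

    def dlogpdf(self, y, params, k):
        return self.dlogpmf(np.asarray(y, float), params, k)

    def _flat(self, y, params):
        """Broadcast y and parameters to a common flat shape."""
        arrs = np.broadcast_arrays(np.asarray(y, float), *[np.asarray(p, float) for p in params])
        shape = arrs[0].shape
        return arrs[0].ravel(), [a.ravel() for a in arrs[1:]], shape

    def _cumgrid(self, weights_fn, yi, params):
        """Column-wise cumulative sums of weights_fn over the grid 0..max(y),
        read out at each observation's own y."""
        Q = max(int(yi.max()), 0)
        grid = np.arange(0.0, Q + 1.0)[:, None]
        pp = [p[None, :] for p in params]
        cs = np.cumsum(weights_fn(grid, pp), axis=0)
        idx = np.clip(yi, 0, Q)
        return cs[idx, np.arange(cs.shape[1])]

    def cdf(self, y, params):
        yf, pf, shape = self._flat(y, params)
        yi = np.floor(yf).astype(int)
        val = self._cumgrid(lambda g, pp: np.exp(self.logpmf(g, pp)), yi, pf)
        out = np.where(yi >= 0, np.minimum(val, 1.0), 0.0)
        return out.reshape(shape)

    def dcdf(self, y, params, k):
        yf, pf, shape = self._flat(y, params)
        yi = np.floor(yf).astype(int)
        val = self._cumgrid(
            lambda g, pp: np.exp(self.logpmf(g, pp)) * self.dlogpmf(g, pp, k), yi, pf
        )
        return np.where(yi >= 0, val, 0.0).reshape(shape)

    def quantile(self, q, params):
        qf, pf, shape = self._flat(q, params)
        Q = 16
        while True:
            grid = np.arange(0.0, Q + 1.0)[:, None]
            pm = np.exp(self.logpmf(grid, [p[None, :] for p in pf]))
            cs = np.cumsum(pm, axis=0)
            hit = cs >= qf[None, :] - 1e-14
            if hit.any(axis=0).all() or Q > 100000:
                break
            Q *= 4
        idx = np.argmax(hit, axis=0).astype(float)
        idx = np.where(hit.any(axis=0), idx, float(Q))
        return idx.reshape(shape)


class Poisson(CountMargin):
    name = "poisson"
    n_params = 1
    param_names = ("mu",)

    def _default_links(self):
        return [LogLink(hi=1e8)]

    def logpmf(self, y, params):
        (mu,) = params
        return -mu + y * np.log(mu) - special.gammaln(y + 1.0)

    def dlogpmf(self, y, params, k):
        (mu,) = params
        return y / mu - 1.0

    def mean(self, params):
        return params[0]


class Geometric(CountMargin):
    """Geometric on {0,1,...} parameterised by its mean mu:
    f(y) = mu^y / (1+mu)^(y+1)."""

    name = "geometric"
    n_params = 1
    param_names = ("mu",)

    def _default_links(self):
        return [LogLink(hi=1e8)]

    def logpmf(self, y, params):
        (mu,) = params
        return y * np.log(mu) - (y + 1.0) * np.log1p(mu)

    def dlogpmf(self, y, params, k):
        (mu,) = params
        return y / mu - (y + 1.0) / (1.0 + mu)

    def mean(self, params):
        return params[0]


class NegBin1(CountMargin):
    """Negative binomial type I: mean mu, variance mu(1 + sigma*mu)."""

    name = "nbinom1"
    n_params = 2
    param_names = ("mu", "sigma")

    def _default_links(self):
        return [LogLink(hi=1e8), LogLink(hi=1e6)]

    def logpmf(self, y, params):
        mu, sg = params
        r = 1.0 / sg
        return (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + y * np.log(sg * mu)
            - (y + r) * np.log1p(sg * mu)
        )

    def dlogpmf(self, y, params, k):
        mu, sg = params
        r = 1.0 / sg
        if k == 0:
            return y / mu - (y + r) * sg / (1.0 + sg * mu)
        return (
            -(special.digamma(y + r) - special.digamma(r)) / sg**2
            + y / sg
            - (y + r) * mu / (1.0 + sg * mu)
            + np.log1p(sg * mu) / sg**2
        )

    def mean(self, params):
        return params[0]


class _ZeroInflated(CountMargin):
    """Zero-inflated mixture: f(0) = nu + (1-nu) g(0), f(y) = (1-nu) g(y).

    The last parameter is the inflation probability nu; the leading ones
    parameterise the base count family g.
    """

    base: CountMargin

    def logpmf(self, y, params):
        nu = params[-1]
        lg = self.base.logpmf(y, params[:-1])
        at0 = np.log(nu + (1.0 - nu) * np.exp(self.base.logpmf(np.zeros_like(y), params[:-1])))
        return np.where(y == 0, at0, np.log1p(-nu) + lg)

    def dlogpmf(self, y, params, k):
        nu = params[-1]
        g0 = np.exp(self.base.logpmf(np.zeros_like(y), params[:-1]))
        f0 = nu + (1.0 - nu) * g0
        if k == self.n_params - 1:
            return np.where(y == 0, (1.0 - g0) / f0, -1.0 / (1.0 - nu))
        dl = self.base.dlogpmf(y, params[:-1], k)
        dl0 = self.base.dlogpmf(np.zeros_like(y), params[:-1], k)
        return np.where(y == 0, (1.0 - nu) * g0 * dl0 / f0, dl)

    def mean(self, params):
        return (1.0 - params[-1]) * self.base.mean(params[:-1])


class ZIPoisson(_ZeroInflated):
    name = "zip"
    n_params = 2
    param_names = ("mu", "nu")
    base = Poisson()

    def _default_links(self):
        return [LogLink(hi=1e8), get_link("logit")]


class ZINegBin(_ZeroInflated):
    name = "zinb"
    n_params = 3
    param_names = ("mu", "sigma", "nu")
    base = NegBin1()

    def _default_links(self):
        return [LogLink(hi=1e8), LogLink(hi=1e6), get_link("logit")]


class ZALogarithmic(CountMargin):
    """Zero-altered (hurdle) logarithmic distribution.

    P(Y=0) = pi0 exactly; on {1,2,...} the logarithmic series
    f(y) = -p^y / (y log(1-p)) scaled by (1 - pi0).  Parameter order is
    (series parameter p, zero probability pi0), so the second parameter
    directly models the probability of a zero.
    """

    name = "zalogarithmic"
    n_params = 2
    param_names = ("p", "pi0")

    def _default_links(self):
        return [get_link("logit"), get_link("logit")]

    def logpmf(self, y, params):
        p, pi0 = params
        L = -np.log1p(-p)
        ysafe = np.maximum(y, 1.0)
        lpos = np.log1p(-pi0) + ysafe * np.log(p) - np.log(ysafe) - np.log(L)
        return np.where(y == 0, np.log(pi0), lpos)

    def dlogpmf(self, y, params, k):
        p, pi0 = params
        if k == 0:
            L = -np.log1p(-p)
            dpos = y / p - 1.0 / (L * (1.0 - p))
            return np.where(y == 0, 0.0, dpos)
        return np.where(y == 0, 1.0 / pi0, -1.0 / (1.0 - pi0))

    def mean(self, params):
        p, pi0 = params
        return (1.0 - pi0) * (-p / ((1.0 - p) * np.log1p(-p)))


class ZANegBin(CountMargin):
    """Zero-altered (hurdle) negative binomial type I.

    P(Y=0) = pi0 exactly; positive part is the zero-truncated NB1 scaled
    by (1 - pi0).  Parameter order: (mu, sigma, pi0).
    """

    name = "zanbinom"
    n_params = 3
    param_names = ("mu", "sigma", "pi0")
    base = NegBin1()

    def _default_links(self):
        return [LogLink(hi=1e8), LogLink(hi=1e6), get_link("logit")]

    def logpmf(self, y, params):
        mu, sg, pi0 = params
        lg = self.base.logpmf(y, [mu, sg])
        g0 = np.exp(self.base.logpmf(np.zeros_like(y), [mu, sg]))
        lpos = np.log1p(-pi0) + lg - np.log1p(-g0)
        return np.where(y == 0, np.log(pi0), lpos)

    def dlogpmf(self, y, params, k):
        mu, sg, pi0 = params
        if k == 2:
            return np.where(y == 0, 1.0 / pi0, -1.0 / (1.0 - pi0))
        g0 = np.exp(self.base.logpmf(np.zeros_like(y), [mu, sg]))
        dl = self.base.dlogpmf(y, [mu, sg], k)
        dl0 = self.base.dlogpmf(np.zeros_like(y), [mu, sg], k)
        dpos = dl + g0 * dl0 / (1.0 - g0)
        return np.where(y == 0, 0.0, dpos)

    def mean(self, params):
        mu, sg, pi0 = params
        g0 = np.exp(self.base.logpmf(np.zeros_like(np.asarray(mu, float)), [mu, sg]))
        return (1.0 - pi0) * mu / (1.0 - g0)


MARGIN_FAMILIES = {
    "bernoulli": Bernoulli,
    "gaussian_hetero": GaussianHetero,
    "poisson": Poisson,
    "geometric": Geometric,
    "nbinom1": NegBin1,
    "zip": ZIPoisson,
    "zinb": ZINegBin,
    "zalogarithmic": ZALogarithmic,
    "zanbinom": ZANegBin,
}


def get_margin(name: str, link: str | None = None) -> Margin:
    """Build a margin from a config name; ``link`` selects the Bernoulli
    response function (logit/probit/cloglog)."""
    key = name.strip().lower()
    if key not in MARGIN_FAMILIES:
        raise ValueError(f"unknown margin family '{name}'; known: {sorted(MARGIN_FAMILIES)}")
    if key == "bernoulli":
        return Bernoulli(link=link or "logit")
    if link is not None:
        raise ValueError("custom links are only selectable for the bernoulli margin")
    return MARGIN_FAMILIES[key]()
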