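"""Link functions mapping additive predictors to distribution parameters.

Each link is a smooth bijection from the real line onto the parameter's
domain.  ``inverse`` is the response function h(eta) -> theta, ``forward``
the link g(theta) -> eta and ``deriv`` the derivative d theta / d eta used
in the chain rule of the score vectors.  Inverse values are clipped to a
numerical box strictly inside the domain; where the clip is active the
derivative is set to zero so that analytic gradients stay consistent with
finite differences of the clipped likelihood.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["Link", "get_link"]


class Link:
    name: str = "abstract"

    def forward(self, theta):
        raise NotImplementedError

    def inverse(self, eta):
        raise NotImplementedError

    def deriv(self, eta):
        """d theta / d eta, zero where the numerical box clips."""
        raise NotImplementedError

    def __repr__(self):  # pragma: no cover
        return f"<link {self.name}>"


class IdentityLink(Link):
    name = "identity"

    def __init__(self, lo=-np.inf, hi=np.inf):
        self.lo, self.hi = lo, hi

    def forward(self, theta):
        return np.asarray(theta, float)

    def inverse(self, eta):
        return np.clip(np.asarray(eta, float), self.lo, self.hi)

    def deriv(self, eta):
        eta = np.asarray(eta, float)
        return np.where((eta > self.lo) & (eta < self.hi), 1.0, 0.0)


class LogLink(Link):
    """theta = exp(eta) + shift, for positive parameters (shift=0) or
    Gumbel-type domains theta > 1 (shift=1)."""

    name = "log"

    def __init__(self, shift=0.0, hi=np.inf, lo=1e-10):
        self.shift, self.hi, self.lo = shift, hi, lo

    def forward(self, theta):
        return np.log(np.maximum(np.asarray(theta, float) - self.shift, 1e-300))

    def inverse(self, eta):
        raw = np.exp(np.clip(np.asarray(eta, float), -700, 700)) + self.shift
        return np.clip(raw, self.shift + self.lo, self.hi)

    def deriv(self, eta):
        eta = np.asarray(eta, float)
        raw = np.exp(np.clip(eta, -700, 700))
        inside = (raw + self.shift > self.shift + self.lo) & (raw + self.shift < self.hi)
        return np.where(inside, raw, 0.0)


class LogitLink(Link):
    name = "logit"
    _box = 1e-10

    def forward(self, theta):
        t = np.clip(np.asarray(theta, float), self._box, 1 - self._box)
        return np.log(t / (1 - t))

    def inverse(self, eta):
        p = special.expit(np.asarray(eta, float))
        return np.clip(p, self._box, 1 - self._box)

    def deriv(self, eta):
        p = special.expit(np.asarray(eta, float))
        inside = (p > self._box) & (p < 1 - self._box)
        return np.where(inside, p * (1 - p), 0.0)


class ProbitLink(Link):
    name = "probit"
    _box = 1e-10

    def forward(self, theta):
        return stats.norm.ppf(np.clip(np.asarray(theta, float), self._box, 1 - self._box))

    def inverse(self, eta):
        return np.clip(stats.norm.cdf(np.asarray(eta, float)), self._box, 1 - self._box)

    def deriv(self, eta):
        eta = np.asarray(eta, float)
        p = stats.norm.cdf(eta)
        inside = (p > self._box) & (p < 1 - self._box)
        return np.where(inside, stats.norm.pdf(eta), 0.0)


class CLogLogLink(Link):
    """theta = 1 - exp(-exp(eta))."""

    name = "cloglog"
    _box = 1e-10

    def forward(self, theta):
        t = np.clip(np.asarray(theta, float), self._box, 1 - self._box)
        return np.log(-np.log1p(-t))

    def inverse(self, eta):
        e = np.exp(np.clip(np.asarray(eta, float), -700, 30))
        return np.clip(-np.expm1(-e), self._box, 1 - self._box)

    def deriv(self, eta):
        eta = np.clip(np.asarray(eta, float), -700, 30)
        e = np.exp(eta)
        p = -np.expm1(-e)
        inside = (p > self._box) & (p < 1 - self._box)
        return np.where(inside, e * np.exp(-e), 0.0)


class TanhLink(Link):
    """theta = scale * tanh(eta); used for (-1,1)-type copula parameters."""

    name = "tanh"

    def __init__(self, scale=1.0, box=1e-7):
        self.scale = scale
        self.box = box

    def forward(self, theta):
        t = np.clip(np.asarray(theta, float) / self.scale, -1 + 1e-15, 1 - 1e-15)
        return np.arctanh(t)

    def inverse(self, eta):
        t = self.scale * np.tanh(np.asarray(eta, float))
        lim = self.scale * (1 - self.box)
        return np.clip(t, -lim, lim)

    def deriv(self, eta):
        eta = np.asarray(eta, float)
        t = np.tanh(eta)
        lim = 1 - self.box
        inside = np.abs(t) < lim
        return np.where(inside, self.scale * (1 - t * t), 0.0)


_REGISTRY = {
    "identity": IdentityLink,
    "log": LogLink,
    "logit": LogitLink,
    "probit": ProbitLink,
    "cloglog": CLogLogLink,
    "tanh": TanhLink,
}


def get_link(name: str, **kwargs) -> Link:
    try:
        return _REGISTRY[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown link '{name}'; choose from {sorted(_REGISTRY)}") from None
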