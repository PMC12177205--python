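"""Joint log-likelihoods of the bivariate copula models and their scores.

Three response configurations are supported:

* ``binary_binary``    -- both margins Bernoulli; the joint pmf is assembled
  from the four cell probabilities, with P(Y1=1, Y2=1) = C(p1, p2; theta).
* ``count_count``      -- both margins counts; the joint pmf is the copula
  rectangle probability C(F1,F2) - C(F1-f1,F2) - C(F1,F2-f2) +
  C(F1-f1,F2-f2), using F - f in place of F(y-1) so the CDF is never
  evaluated at a negative argument.
* ``binary_continuous``-- latent-variable representation: the binary margin
  enters through F1(0) = 1 - p and the likelihood uses the conditional
  copula CDF h = dC(F1(0), F2(y2))/dF2.

``gradients`` returns d l_i / d eta_k for every additive predictor, fully
analytic via the chain rule through the margin CDF/density derivatives, the
copula partial derivatives and the link derivatives.  A finite-difference
fallback (``grad_method='fd'``) exists for cross-checks.
"""

from __future__ import annotations

import numpy as np

from .copulas import Copula, get_copula
from .margins import Margin, get_margin

__all__ = ["BivariateCopulaModel", "UnivariateModel", "infer_response_kind"]

_PCLIP = 1e-15  # lower clip on probabilities entering a log


def infer_response_kind(margin1: Margin, margin2: Margin) -> str:
    pair = (margin1.support, margin2.support)
    if pair == ("binary", "binary"):
        return "binary_binary"
    if pair == ("count", "count"):
        return "count_count"
    if pair == ("binary", "continuous"):
        return "binary_continuous"
    raise ValueError(
        f"unsupported margin support combination {pair}; the binary margin "
        "must be the first component of a mixed model"
    )


class UnivariateModel:
    """A single margin with per-parameter additive predictors.

    Shares the likelihood/gradient interface of ``BivariateCopulaModel`` so
    the boosting engine can fit independent univariate benchmarks.
    """

    def __init__(self, margin: Margin | str):
        self.margin = get_margin(margin) if isinstance(margin, str) else margin
        self.K = self.margin.n_params
        self.param_labels = [f"{self.margin.name}.{p}" for p in self.margin.param_names]

    def validate(self, y):
        return self.margin.validate(np.asarray(y).reshape(-1))

    def _params(self, eta):
        return self.margin.params_from_eta([eta[:, k] for k in range(self.K)])

    def loglik(self, y, eta):
        return self.margin.logpdf(self.validate(y), self._params(eta))

    def gradients(self, y, eta):
        y = self.validate(y)
        params = self._params(eta)
        dpe = self.margin.dparams_deta([eta[:, k] for k in range(self.K)])
        out = np.empty((len(y), self.K))
        for k in range(self.K):
            out[:, k] = self.margin.dlogpdf(y, params, k) * dpe[k]
        return out

    def empirical_risk(self, y, eta, weights=None):
        ll = self.loglik(y, eta)
        if weights is None:
            return -float(np.mean(ll))
        w = np.asarray(weights, float)
        return -float(np.sum(w * ll) / np.sum(w))

    def predictive_params(self, eta):
        return self._params(eta)


class BivariateCopulaModel:
    """Two parametric margins coupled by a one-parameter copula.

    Parameters are ordered (margin-1 params, margin-2 params, copula), so the
    predictor matrix ``eta`` has K = K1 + K2 + 1 columns.
    """

    def __init__(self, margin1, margin2, copula, response_kind: str | None = None):
        self.margin1 = get_margin(margin1) if isinstance(margin1, str) else margin1
        self.margin2 = get_margin(margin2) if isinstance(margin2, str) else margin2
        self.copula: Copula = get_copula(copula) if isinstance(copula, str) else copula
        kind = infer_response_kind(self.margin1, self.margin2)
        if response_kind is not None and response_kind != kind:
            raise ValueError(
                f"declared response_kind '{response_kind}' inconsistent with margins ('{kind}')"
            )
        self.response_kind = kind
        self.K1 = self.margin1.n_params
        self.K2 = self.margin2.n_params
        self.K = self.K1 + self.K2 + 1
        rot = str(self.copula.rotation) if self.copula.rotation else ""
        self.param_labels = (
            [f"m1.{p}" for p in self.margin1.param_names]
            + [f"m2.{p}" for p in self.margin2.param_names]
            + [f"copula.{self.copula.name}{rot}"]
        )

    # -- plumbing -------------------------------------------------------------
    def validate(self, y):
        y = np.asarray(y, float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("responses must be an (n, 2) array")
        self.margin1.validate(y[:, 0])
        self.margin2.validate(y[:, 1])
        return y

    def split_eta(self, eta):
        eta = np.asarray(eta, float)
        if eta.ndim != 2 or eta.shape[1] != self.K:
            raise ValueError(f"eta must have {self.K} columns")
        e1 = [eta[:, k] for k in range(self.K1)]
        e2 = [eta[:, self.K1 + k] for k in range(self.K2)]
        return e1, e2, eta[:, -1]

    def natural_params(self, eta):
        e1, e2, ec = self.split_eta(eta)
        return (
            self.margin1.params_from_eta(e1),
            self.margin2.params_from_eta(e2),
            self.copula.theta_from_eta(ec),
        )

    # -- likelihoods -----------------------------------------------------------
    def loglik(self, y, eta):
        y = self.validate(y)
        p1, p2, th = self.natural_params(eta)
        if self.response_kind == "binary_binary":
            return self._ll_binary(y, p1[0], p2[0], th)[0]
        if self.response_kind == "count_count":
            return self._ll_count(y, p1, p2, th)[0]
        return self._ll_mixed(y, p1[0], p2, th)[0]

    def empirical_risk(self, y, eta, weights=None):
        ll = self.loglik(y, eta)
        if weights is None:
            return -float(np.mean(ll))
        w = np.asarray(weights, float)
        return -float(np.sum(w * ll) / np.sum(w))

    def _ll_binary(self, y, p1, p2, th):
        y1, y2 = y[:, 0], y[:, 1]
        p11 = self.copula.cdf(p1, p2, th)
        cells = {
            "a11": np.maximum(p11, _PCLIP),
            "a10": np.maximum(p1 - p11, _PCLIP),
            "a01": np.maximum(p2 - p11, _PCLIP),
            "a00": np.maximum(1.0 - p1 - p2 + p11, _PCLIP),
        }
        ll = (
            y1 * y2 * np.log(cells["a11"])
            + y1 * (1 - y2) * np.log(cells["a10"])
            + (1 - y1) * y2 * np.log(cells["a01"])
            + (1 - y1) * (1 - y2) * np.log(cells["a00"])
        )
        return ll, cells

    def _count_blocks(self, y, p1, p2):
        y1, y2 = y[:, 0], y[:, 1]
        F1, f1 = self.margin1.cdf(y1, p1), self.margin1.pdf(y1, p1)
        F2, f2 = self.margin2.cdf(y2, p2), self.margin2.pdf(y2, p2)
        return (y1, y2, F1, f1, F1 - f1, F2, f2, F2 - f2)

    def _ll_count(self, y, p1, p2, th):
        y1, y2, F1, f1, F1m, F2, f2, F2m = self._count_blocks(y, p1, p2)
        C = self.copula.cdf
        R = C(F1, F2, th) - C(F1m, F2, th) - C(F1, F2m, th) + C(F1m, F2m, th)
        R = np.maximum(R, _PCLIP)
        return np.log(R), R

    def _ll_mixed(self, y, p, p2, th):
        y1, y2 = y[:, 0], y[:, 1]
        u = 1.0 - p  # F1(0), CDFs of binary and latent variable coincide at 0
        v = self.margin2.cdf(y2, p2)
        h = self.copula.hfun(u, v, th, wrt="v")
        h = np.clip(h, _PCLIP, 1.0 - _PCLIP)
        lf2 = self.margin2.logpdf(y2, p2)
        return (1 - y1) * np.log(h) + y1 * np.log1p(-h) + lf2, h

    # -- analytic scores ---------------------------------------------------------
    def gradients(self, y, eta, method="analytic"):
        """n x K matrix of d l_i / d eta_k (the negative gradient of the
        per-observation loss)."""
        if method == "fd":
            return self._gradients_fd(y, eta)
        y = self.validate(y)
        e1, e2, ec = self.split_eta(eta)
        p1 = self.margin1.params_from_eta(e1)
        p2 = self.margin2.params_from_eta(e2)
        th = self.copula.theta_from_eta(ec)
        d1 = self.margin1.dparams_deta(e1)
        d2 = self.margin2.dparams_deta(e2)
        dth = self.copula.dtheta_deta(ec)
        if self.response_kind == "binary_binary":
            return self._grad_binary(y, p1[0], p2[0], th, d1[0], d2[0], dth)
        if self.response_kind == "count_count":
            return self._grad_count(y, p1, p2, th, d1, d2, dth)
        return self._grad_mixed(y, p1[0], p2, th, d1[0], d2, dth)

    def _grad_binary(self, y, p1, p2, th, d1, d2, dth):
        y1, y2 = y[:, 0], y[:, 1]
        _, cells = self._ll_binary(y, p1, p2, th)
        a11, a10, a01, a00 = cells["a11"], cells["a10"], cells["a01"], cells["a00"]
        w11 = y1 * y2 / a11 - y1 * (1 - y2) / a10 - (1 - y1) * y2 / a01 + (1 - y1) * (1 - y2) / a00
        cu = self.copula.hfun(p1, p2, th, wrt="u")
        cv = self.copula.hfun(p1, p2, th, wrt="v")
        ct = self.copula.dtheta(p1, p2, th)
        g = np.empty((len(y1), 3))
        g[:, 0] = (y1 * (1 - y2) / a10 - (1 - y1) * (1 - y2) / a00 + w11 * cu) * d1
        g[:, 1] = ((1 - y1) * y2 / a01 - (1 - y1) * (1 - y2) / a00 + w11 * cv) * d2
        g[:, 2] = w11 * ct * dth
        return g

    def _grad_count(self, y, p1, p2, th, d1, d2, dth):
        y1, y2, F1, f1, F1m, F2, f2, F2m = self._count_blocks(y, p1, p2)
        _, R = self._ll_count(y, p1, p2, th)
        hu, hv, ct = (
            lambda a, b: self.copula.hfun(a, b, th, wrt="u"),
            lambda a, b: self.copula.hfun(a, b, th, wrt="v"),
            lambda a, b: self.copula.dtheta(a, b, th),
        )
        n = len(y1)
        g = np.empty((n, self.K))
        # margin 1 parameters
        for k in range(self.K1):
            dF1 = self.margin1.dcdf(y1, p1, k)
            dF1m = dF1 - f1 * self.margin1.dlogpdf(y1, p1, k)
            dR = (
                hu(F1, F2) * dF1
                - hu(F1m, F2) * dF1m
                - hu(F1, F2m) * dF1
                + hu(F1m, F2m) * dF1m
            )
            g[:, k] = dR / R * d1[k]
        # margin 2 parameters
        for k in range(self.K2):
            dF2 = self.margin2.dcdf(y2, p2, k)
            dF2m = dF2 - f2 * self.margin2.dlogpdf(y2, p2, k)
            dR = (
                hv(F1, F2) * dF2
                - hv(F1m, F2) * dF2
                - hv(F1, F2m) * dF2m
                + hv(F1m, F2m) * dF2m
            )
            g[:, self.K1 + k] = dR / R * d2[k]
        dR = ct(F1, F2) - ct(F1m, F2) - ct(F1, F2m) + ct(F1m, F2m)
        g[:, -1] = dR / R * dth
        return g

    def _grad_mixed(self, y, p, p2, th, d1, d2, dth):
        y1, y2 = y[:, 0], y[:, 1]
        u = 1.0 - p
        v = self.margin2.cdf(y2, p2)
        h, dh_du, dh_dv, dh_dt = self.copula.hv_block(u, v, th)
        h = np.clip(h, _PCLIP, 1.0 - _PCLIP)
        w = (1 - y1) / h - y1 / (1.0 - h)
        g = np.empty((len(y1), self.K))
        g[:, 0] = w * dh_du * (-d1)
        for k in range(self.K2):
            dF2 = self.margin2.dcdf(y2, p2, k)
            dlf2 = self.margin2.dlogpdf(y2, p2, k)
            g[:, 1 + k] = (w * dh_dv * dF2 + dlf2) * d2[k]
        g[:, -1] = w * dh_dt * dth
        return g

    def _gradients_fd(self, y, eta, h=None):
        eta = np.asarray(eta, float)
        g = np.empty_like(eta)
        for k in range(self.K):
            step = 1e-6 * np.maximum(1.0, np.abs(eta[:, k])) if h is None else h
            ep, em = eta.copy(), eta.copy()
            ep[:, k] += step
            em[:, k] -= step
            g[:, k] = (self.loglik(y, ep) - self.loglik(y, em)) / (2 * step)
        return g

    # -- predictive quantities -----------------------------------------------------
    def tau(self, eta):
        """Per-observation Kendall's tau implied by the copula predictor."""
        _, _, ec = self.split_eta(eta)
        return self.copula.tau(self.copula.theta_from_eta(ec))

    def joint_cdf(self, y1, y2, eta):
        """P(Y1 <= y1, Y2 <= y2)."""
        if self.response_kind == "binary_binary":
            return self.joint_prob(eta, (("le", np.min(y1)), ("le", np.min(y2))))
        p1, p2, th = self.natural_params(eta)
        F1 = self.margin1.cdf(np.asarray(y1, float), p1)
        F2 = self.margin2.cdf(np.asarray(y2, float), p2)
        return self.copula.cdf(F1, F2, th)

    def joint_prob(self, eta, event):
        """Probability of a rectangle/cell event.

        ``event`` is a pair; each entry is either a value y (meaning Y = y
        for discrete margins) or a tuple ("le", q) meaning Y <= q.
        """
        p1, p2, th = self.natural_params(eta)
        n = len(th) if np.ndim(th) else 1

        if self.response_kind == "binary_binary":
            # the binary model couples the success probabilities directly,
            # so cell probabilities come from the same construction as the
            # likelihood rather than from a CDF rectangle
            p11 = self.copula.cdf(p1[0], p2[0], th)
            cells = {
                (1, 1): p11,
                (1, 0): p1[0] - p11,
                (0, 1): p2[0] - p11,
                (0, 0): 1.0 - p1[0] - p2[0] + p11,
            }

            def values(spec):
                if isinstance(spec, tuple) and spec[0] == "le":
                    return (0, 1) if spec[1] >= 1 else (0,)
                return (int(spec),)

            total = np.zeros(n)
            for a in values(event[0]):
                for b in values(event[1]):
                    total += cells[(a, b)]
            return np.clip(total, 0.0, 1.0)

        def bounds(margin, params, spec):
            if isinstance(spec, tuple) and spec[0] == "le":
                hi = margin.cdf(np.full(n, float(spec[1])), params)
                return np.zeros(n), hi
            yv = np.full(n, float(spec))
            hi = margin.cdf(yv, params)
            return hi - margin.pdf(yv, params), hi

        lo1, hi1 = bounds(self.margin1, p1, event[0])
        lo2, hi2 = bounds(self.margin2, p2, event[1])
        C = self.copula.cdf
        R = C(hi1, hi2, th) - C(lo1, hi2, th) - C(hi1, lo2, th) + C(lo1, lo2, th)
        return np.maximum(R, 0.0)
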