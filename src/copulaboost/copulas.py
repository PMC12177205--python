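"""One-parameter bivariate copula families.

Implements the Gaussian, Clayton, Gumbel, Frank, Farlie-Gumbel-Morgenstern
(FGM) and Ali-Mikhail-Haq (AMH) copulas plus 90/180/270 degree rotations.
Each family exposes the CDF C(u,v;theta), the conditional distribution
functions ("h-functions") dC/du and dC/dv, the copula density, the
derivative dC/dtheta, second-order partials of the v-h-function (needed by
the mixed binary-continuous score), the link from the additive predictor to
the copula parameter and the closed-form Kendall's tau map.

All evaluators are vectorised over observations with observation-specific
parameters; u, v are clipped to [1e-12, 1-1e-12] and theta to a per-family
numerical box before evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

from .links import IdentityLink, LogLink, TanhLink

__all__ = ["Copula", "get_copula", "COPULA_FAMILIES"]

_EPS = 1e-12


def _clip_uv(x):
    return np.clip(np.asarray(x, float), _EPS, 1.0 - _EPS)


class Copula:
    """Abstract one-parameter copula.

    Subclasses implement the raw evaluators on clipped arguments.  Public
    methods clip inputs and validate the parameter domain.
    """

    name: str = "abstract"
    rotation: int = 0
    #: closed theta domain used for validation (mathematical domain)
    theta_domain: tuple = (-np.inf, np.inf)
    #: numerical clipping box strictly inside the domain
    theta_box: tuple = (-np.inf, np.inf)
    #: value of theta at (or towards) which the family is independence
    independence_theta: float = 0.0
    link = IdentityLink()

    # -- raw evaluators (clipped args) ------------------------------------
    def _cdf(self, u, v, t):
        raise NotImplementedError

    def _hv(self, u, v, t):
        """dC/dv."""
        raise NotImplementedError

    def _dhv_du(self, u, v, t):
        """d2C/du dv = copula density."""
        raise NotImplementedError

    def _dhv_dv(self, u, v, t):
        """d2C/dv2."""
        raise NotImplementedError

    def _dhv_dt(self, u, v, t):
        """d2C/dv dtheta."""
        raise NotImplementedError

    def _dcdf_dt(self, u, v, t):
        raise NotImplementedError

    def _tau(self, t):
        raise NotImplementedError

    # -- public API --------------------------------------------------------
    def _prep(self, u, v, theta):
        u, v = _clip_uv(u), _clip_uv(v)
        theta = np.asarray(theta, float)
        lo, hi = self.theta_domain
        if np.any(theta < lo) or np.any(theta > hi):
            raise ValueError(
                f"copula parameter outside domain [{lo}, {hi}] for family '{self.name}'"
            )
        t = np.clip(theta, self.theta_box[0], self.theta_box[1])
        u, v, t = np.broadcast_arrays(u, v, t)
        return u, v, t

    def cdf(self, u, v, theta):
        u, v, t = self._prep(u, v, theta)
        return np.clip(self._cdf(u, v, t), 0.0, 1.0)

    def hfun(self, u, v, theta, wrt="u"):
        """Conditional CDF: dC/du (wrt='u') or dC/dv (wrt='v')."""
        u, v, t = self._prep(u, v, theta)
        if wrt == "v":
            h = self._hv(u, v, t)
        elif wrt == "u":
            h = self._hu(u, v, t)
        else:
            raise ValueError("wrt must be 'u' or 'v'")
        return np.clip(h, 0.0, 1.0)

    def _hu(self, u, v, t):
        # all base families here are exchangeable
        return self._hv(v, u, t)

    def density(self, u, v, theta):
        u, v, t = self._prep(u, v, theta)
        return np.maximum(self._dhv_du(u, v, t), 0.0)

    def dtheta(self, u, v, theta):
        """dC/dtheta in the family's own parameter units."""
        u, v, t = self._prep(u, v, theta)
        return self._dcdf_dt(u, v, t)

    def hv_block(self, u, v, theta):
        """dC/dv together with its partials (du, dv, dtheta).

        Used by the latent-variable mixed-response score, which needs the
        full derivative structure of the conditional CDF.
        """
        u, v, t = self._prep(u, v, theta)
        return (
            np.clip(self._hv(u, v, t), 0.0, 1.0),
            self._dhv_du(u, v, t),
            self._dhv_dv(u, v, t),
            self._dhv_dt(u, v, t),
        )

    def tau(self, theta):
        theta = np.asarray(theta, float)
        lo, hi = self.theta_domain
        if np.any(theta < lo) or np.any(theta > hi):
            raise ValueError(f"copula parameter outside domain for '{self.name}'")
        t = np.clip(theta, self.theta_box[0], self.theta_box[1])
        return self._tau(t)

    def theta_from_eta(self, eta):
        return self.link.inverse(eta)

    def dtheta_deta(self, eta):
        return self.link.deriv(eta)

    def rotate(self, angle):
        if angle not in (90, 180, 270):
            raise ValueError("rotation angle must be one of 90, 180, 270")
        return RotatedCopula(self, angle)

    def __repr__(self):  # pragma: no cover
        tag = f"{self.rotation}" if self.rotation else ""
        return f"<copula {self.name}{tag}>"


# ---------------------------------------------------------------------------
# Gaussian
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _bvn_density(x, y, r):
    s2 = 1.0 - r * r
    z = (x * x - 2.0 * r * x * y + y * y) / s2
    return np.exp(-0.5 * z) / (2.0 * np.pi * np.sqrt(s2))


class GaussianCopula(Copula):
    """Gaussian copula; theta is the correlation rho in (-1, 1).

    The CDF uses the identity Phi2(x,y;rho) = Phi(x)Phi(y) +
    int_0^rho phi2(x,y;r) dr evaluated with fixed Gauss-Legendre nodes,
    which makes dC/drho = phi2(x,y;rho) exactly consistent.
    """

    name = "gaussian"
    theta_domain = (-1.0, 1.0)
    theta_box = (-(1 - 1e-7), 1 - 1e-7)
    independence_theta = 0.0
    link = TanhLink()

    def _cdf(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        # integrate phi2 over r in [0, t] per observation
        half = t / 2.0
        r = half[..., None] * (_GL_NODES + 1.0)  # nodes in [0, t]
        w = half[..., None] * _GL_WEIGHTS
        integ = np.sum(w * _bvn_density(x[..., None], y[..., None], r), axis=-1)
        return u * v + integ

    def _hv(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        s = np.sqrt(1.0 - t * t)
        return stats.norm.cdf((x - t * y) / s)

    def _dhv_du(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        s = np.sqrt(1.0 - t * t)
        w = (x - t * y) / s
        return stats.norm.pdf(w) / (s * stats.norm.pdf(x))

    def _dhv_dv(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        s = np.sqrt(1.0 - t * t)
        w = (x - t * y) / s
        return -t * stats.norm.pdf(w) / (s * stats.norm.pdf(y))

    def _dhv_dt(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        s = np.sqrt(1.0 - t * t)
        w = (x - t * y) / s
        dw = (t * x - y) / (s * s * s)
        return stats.norm.pdf(w) * dw

    def _dcdf_dt(self, u, v, t):
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        return _bvn_density(x, y, t)

    def _tau(self, t):
        return 2.0 / np.pi * np.arcsin(t)


# ---------------------------------------------------------------------------
# Clayton
# ---------------------------------------------------------------------------


class ClaytonCopula(Copula):
    """Clayton copula, theta > 0, lower tail dependence.

    Evaluated in log space to avoid overflow of u**(-theta); the removable
    singularity at theta -> 0 (independence) is handled by a series branch.
    """

    name = "clayton"
    theta_domain = (0.0, np.inf)
    theta_box = (0.0, 30.0)
    independence_theta = 0.0
    link = LogLink(hi=30.0)
    _indep_tol = 1e-6

    @staticmethod
    def _logS(u, v, t):
        ts = np.maximum(t, 1e-300)
        a, b = -ts * np.log(u), -ts * np.log(v)  # >= 0
        m = np.maximum(a, b)
        return m + np.log(np.exp(a - m) + np.exp(b - m) - np.exp(-m))

    def _cdf(self, u, v, t):
        tsm = np.where(t < self._indep_tol, t, 0.0)
        out = u * v * np.exp(tsm * np.log(u) * np.log(v))
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            c = np.exp(-self._logS(u, v, ts) / ts)
            out = np.where(big, c, out)
        return out

    def _hv(self, u, v, t):
        # v^(-t-1) * S^(-1/t - 1)
        tsm = np.where(t < self._indep_tol, t, 0.0)
        small = u * (1.0 + tsm * np.log(u) * (np.log(v) + 1.0))
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            logS = self._logS(u, v, ts)
            h = np.exp(-(ts + 1.0) * np.log(v) - (1.0 / ts + 1.0) * logS)
            small = np.where(big, h, small)
        return small

    def _dhv_du(self, u, v, t):
        out = np.ones_like(u)
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            logS = self._logS(u, v, ts)
            logc = (
                np.log1p(ts)
                - (ts + 1.0) * (np.log(u) + np.log(v))
                - (1.0 / ts + 2.0) * logS
            )
            out = np.where(big, np.exp(logc), out)
        return out

    def _dhv_dv(self, u, v, t):
        out = np.zeros_like(u)
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            logS = self._logS(u, v, ts)
            t1 = -(ts + 1.0) * np.exp(-(ts + 2.0) * np.log(v) - (1.0 / ts + 1.0) * logS)
            t2 = (1.0 + ts) * np.exp(-(2.0 * ts + 2.0) * np.log(v) - (1.0 / ts + 2.0) * logS)
            out = np.where(big, t1 + t2, out)
        return out

    def _dhv_dt(self, u, v, t):
        out = u * np.log(u) * (np.log(v) + 1.0)
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            logS = self._logS(u, v, ts)
            # S_t = d S / d theta = -(u^-t log u + v^-t log v)
            St = -(
                np.exp(-ts * np.log(u)) * np.log(u)
                + np.exp(-ts * np.log(v)) * np.log(v)
            )
            hv = np.exp(-(ts + 1.0) * np.log(v) - (1.0 / ts + 1.0) * logS)
            dlog = -np.log(v) + logS / ts**2 - (1.0 / ts + 1.0) * St * np.exp(-logS)
            out = np.where(big, hv * dlog, out)
        return out

    def _dcdf_dt(self, u, v, t):
        out = u * v * np.log(u) * np.log(v)
        big = t >= self._indep_tol
        if np.any(big):
            ts = np.where(big, t, 1.0)
            logS = self._logS(u, v, ts)
            St = -(
                np.exp(-ts * np.log(u)) * np.log(u)
                + np.exp(-ts * np.log(v)) * np.log(v)
            )
            c = np.exp(-logS / ts)
            d = c * (logS / ts**2 - St * np.exp(-logS) / ts)
            out = np.where(big, d, out)
        return out

    def _tau(self, t):
        return t / (t + 2.0)


# ---------------------------------------------------------------------------
# Gumbel
# ---------------------------------------------------------------------------


class GumbelCopula(Copula):
    """Gumbel copula, theta >= 1, upper tail dependence (log-space)."""

    name = "gumbel"
    theta_domain = (1.0, np.inf)
    theta_box = (1.0, 30.0)
    independence_theta = 1.0
    link = LogLink(shift=1.0, hi=30.0, lo=1e-12)

    @staticmethod
    def _parts(u, v, t):
        lx, ly = np.log(-np.log(u)), np.log(-np.log(v))  # log x, log y
        a, b = t * lx, t * ly
        m = np.maximum(a, b)
        logS = m + np.log(np.exp(a - m) + np.exp(b - m))
        A = np.exp(logS / t)
        return lx, ly, logS, A

    def _cdf(self, u, v, t):
        _, _, _, A = self._parts(u, v, t)
        return np.exp(-A)

    def _hv(self, u, v, t):
        lx, ly, logS, A = self._parts(u, v, t)
        # C * S^(1/t - 1) * y^(t-1) / v
        return np.exp(-A + (1.0 / t - 1.0) * logS + (t - 1.0) * ly - np.log(v))

    def _dhv_du(self, u, v, t):
        lx, ly, logS, A = self._parts(u, v, t)
        hv = -A + (1.0 / t - 1.0) * logS + (t - 1.0) * ly - np.log(v)
        # d log hv / du = S^(1/t-1) x^(t-1)/u + (1-1/t) t x^(t-1)/(S u)
        dA_du = -np.exp((1.0 / t - 1.0) * logS + (t - 1.0) * lx - np.log(u))
        dlogS_du = -t * np.exp((t - 1.0) * lx - logS) / u
        dlog = -dA_du + (1.0 / t - 1.0) * dlogS_du
        return np.exp(hv) * dlog

    def _dhv_dv(self, u, v, t):
        lx, ly, logS, A = self._parts(u, v, t)
        hv = np.exp(-A + (1.0 / t - 1.0) * logS + (t - 1.0) * ly - np.log(v))
        dA_dv = -np.exp((1.0 / t - 1.0) * logS + (t - 1.0) * ly - np.log(v))
        dlogS_dv = -t * np.exp((t - 1.0) * ly - logS) / v
        dlog = (
            -dA_dv
            + (1.0 / t - 1.0) * dlogS_dv
            + (t - 1.0) * (-1.0 / (v * (-np.log(v))))
            - 1.0 / v
        )
        return hv * dlog

    def _dhv_dt(self, u, v, t):
        lx, ly, logS, A = self._parts(u, v, t)
        hv = np.exp(-A + (1.0 / t - 1.0) * logS + (t - 1.0) * ly - np.log(v))
        # dS/dt = x^t log x + y^t log y  -> dlogS/dt
        dlogS_dt = (np.exp(t * lx - logS) * lx + np.exp(t * ly - logS) * ly)
        dA_dt = A * (-logS / t**2 + dlogS_dt / t)
        dlog = -dA_dt - logS / t**2 + (1.0 / t - 1.0) * dlogS_dt + ly
        return hv * dlog

    def _dcdf_dt(self, u, v, t):
        lx, ly, logS, A = self._parts(u, v, t)
        dlogS_dt = (np.exp(t * lx - logS) * lx + np.exp(t * ly - logS) * ly)
        dA_dt = A * (-logS / t**2 + dlogS_dt / t)
        return -np.exp(-A) * dA_dt

    def _tau(self, t):
        return 1.0 - 1.0 / t


# ---------------------------------------------------------------------------
# Frank
# ---------------------------------------------------------------------------


class FrankCopula(Copula):
    """Frank copula, theta in R \\ {0}; theta = 0 handled as the
    independence limit (series branch)."""

    name = "frank"
    theta_domain = (-np.inf, np.inf)
    theta_box = (-35.0, 35.0)
    independence_theta = 0.0
    link = IdentityLink(lo=-35.0, hi=35.0)
    _indep_tol = 1e-8

    @staticmethod
    def _g(x, t):
        return np.expm1(-t * x)

    def _split(self, t):
        big = np.abs(t) >= self._indep_tol
        ts = np.where(big, t, 1.0)
        return big, ts

    def _cdf(self, u, v, t):
        big, ts = self._split(t)
        D = 1.0 + self._g(u, ts) * self._g(v, ts) / self._g(1.0, ts)
        out = -np.log(np.maximum(D, 1e-300)) / ts
        small = u * v * (1.0 + t * (1.0 - u) * (1.0 - v) / 2.0)
        return np.where(big, out, small)

    def _hv(self, u, v, t):
        big, ts = self._split(t)
        gu, gv, g1 = self._g(u, ts), self._g(v, ts), self._g(1.0, ts)
        D = g1 + gu * gv
        out = np.exp(-ts * v) * gu / D
        small = u * (1.0 + t * (1.0 - u) * (1.0 - 2.0 * v) / 2.0)
        return np.where(big, out, small)

    def _dhv_du(self, u, v, t):
        big, ts = self._split(t)
        gu, gv, g1 = self._g(u, ts), self._g(v, ts), self._g(1.0, ts)
        D = g1 + gu * gv
        out = -ts * np.exp(-ts * (u + v)) * g1 / (D * D)
        small = 1.0 + t * (1.0 - 2.0 * u) * (1.0 - 2.0 * v) / 2.0
        return np.where(big, out, small)

    def _dhv_dv(self, u, v, t):
        big, ts = self._split(t)
        gu, gv, g1 = self._g(u, ts), self._g(v, ts), self._g(1.0, ts)
        D = g1 + gu * gv
        e = np.exp(-ts * v)
        out = -ts * e * gu / D + ts * e * e * gu * gu / (D * D)
        small = -t * u * (1.0 - u)
        return np.where(big, out, small)

    def _dhv_dt(self, u, v, t):
        big, ts = self._split(t)
        gu, gv, g1 = self._g(u, ts), self._g(v, ts), self._g(1.0, ts)
        D = g1 + gu * gv
        e = np.exp(-ts * v)
        N = e * gu
        dN = -v * e * gu + e * (-u * np.exp(-ts * u))
        dD = -np.exp(-ts) + (-u * np.exp(-ts * u)) * gv + gu * (-v * np.exp(-ts * v))
        out = (dN * D - N * dD) / (D * D)
        small = u * (1.0 - u) * (1.0 - 2.0 * v) / 2.0
        return np.where(big, out, small)

    def _dcdf_dt(self, u, v, t):
        big, ts = self._split(t)
        gu, gv, g1 = self._g(u, ts), self._g(v, ts), self._g(1.0, ts)
        D = 1.0 + gu * gv / g1
        # C = -log(D)/t
        dgu, dgv, dg1 = -u * np.exp(-ts * u), -v * np.exp(-ts * v), -np.exp(-ts)
        dD = (dgu * gv + gu * dgv) / g1 - gu * gv * dg1 / (g1 * g1)
        out = np.log(np.maximum(D, 1e-300)) / ts**2 - dD / (ts * D)
        small = u * v * (1.0 - u) * (1.0 - v) / 2.0
        return np.where(big, out, small)

    def _tau(self, t):
        t = np.asarray(t, float)

        def one(th):
            a = abs(th)
            if a < 1e-6:
                return th / 9.0
            debye, _ = integrate.quad(lambda s: s / np.expm1(s), 0.0, a)
            val = 1.0 - 4.0 / a * (1.0 - debye / a)
            return np.sign(th) * val

        return np.vectorize(one, otypes=[float])(t)


# ---------------------------------------------------------------------------
# FGM and AMH
# ---------------------------------------------------------------------------


class FGMCopula(Copula):
    """Farlie-Gumbel-Morgenstern copula, theta in [-1, 1] (weak dependence)."""

    name = "fgm"
    theta_domain = (-1.0, 1.0)
    theta_box = (-1.0, 1.0)
    independence_theta = 0.0
    link = TanhLink(box=0.0)

    def _cdf(self, u, v, t):
        return u * v * (1.0 + t * (1.0 - u) * (1.0 - v))

    def _hv(self, u, v, t):
        return u * (1.0 + t * (1.0 - u) * (1.0 - 2.0 * v))

    def _dhv_du(self, u, v, t):
        return 1.0 + t * (1.0 - 2.0 * u) * (1.0 - 2.0 * v)

    def _dhv_dv(self, u, v, t):
        return -2.0 * t * u * (1.0 - u)

    def _dhv_dt(self, u, v, t):
        return u * (1.0 - u) * (1.0 - 2.0 * v)

    def _dcdf_dt(self, u, v, t):
        return u * v * (1.0 - u) * (1.0 - v)

    def _tau(self, t):
        return 2.0 * t / 9.0


class AMHCopula(Copula):
    """Ali-Mikhail-Haq copula, theta in [-1, 1)."""

    name = "amh"
    theta_domain = (-1.0, 1.0)
    theta_box = (-0.999999, 0.999999)
    independence_theta = 0.0
    link = TanhLink(scale=0.99, box=0.0)

    @staticmethod
    def _E(u, v, t):
        return 1.0 - t * (1.0 - u) * (1.0 - v)

    def _cdf(self, u, v, t):
        return u * v / self._E(u, v, t)

    def _hv(self, u, v, t):
        E = self._E(u, v, t)
        return u / E - t * u * (1.0 - u) * v / (E * E)

    def _dhv_du(self, u, v, t):
        E = self._E(u, v, t)
        return (
            1.0 / E
            - t * u * (1.0 - v) / (E * E)
            - t * v * (1.0 - 2.0 * u) / (E * E)
            + 2.0 * t * t * u * (1.0 - u) * v * (1.0 - v) / (E * E * E)
        )

    def _dhv_dv(self, u, v, t):
        E = self._E(u, v, t)
        return (
            -2.0 * t * u * (1.0 - u) / (E * E)
            + 2.0 * t * t * u * v * (1.0 - u) ** 2 / (E * E * E)
        )

    def _dhv_dt(self, u, v, t):
        E = self._E(u, v, t)
        a = u * (1.0 - u) * (1.0 - v) / (E * E)
        b = -u * (1.0 - u) * v / (E * E)
        c = -2.0 * t * u * (1.0 - u) ** 2 * v * (1.0 - v) / (E * E * E)
        return a + b + c

    def _dcdf_dt(self, u, v, t):
        E = self._E(u, v, t)
        return u * v * (1.0 - u) * (1.0 - v) / (E * E)

    def _tau(self, t):
        t = np.asarray(t, float)
        small = np.abs(t) < 1e-4
        ts = np.where(small, 0.5, t)
        full = 1.0 - 2.0 * (ts + (1.0 - ts) ** 2 * np.log1p(-ts)) / (3.0 * ts * ts)
        series = 2.0 * t / 9.0 + t * t / 18.0
        return np.where(small, series, full)


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------


class RotatedCopula(Copula):
    """Counter-clockwise rotation of a base copula.

    C90(u,v)  = v - C(1-u, v)
    C180(u,v) = u + v - 1 + C(1-u, 1-v)   (survival copula)
    C270(u,v) = u - C(u, 1-v)

    90/270 rotations of positive-dependence families (Clayton, Gumbel)
    model negative dependence; Kendall's tau flips sign.
    """

    def __init__(self, base: Copula, angle: int):
        if angle not in (90, 180, 270):
            raise ValueError("rotation angle must be one of 90, 180, 270")
        if base.rotation != 0:
            raise ValueError("cannot rotate an already-rotated copula")
        self.base = base
        self.rotation = angle
        self.name = base.name
        self.theta_domain = base.theta_domain
        self.theta_box = base.theta_box
        self.independence_theta = base.independence_theta
        self.link = base.link

    def _cdf(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return v - b._cdf(1 - u, v, t)
        if self.rotation == 180:
            return u + v - 1 + b._cdf(1 - u, 1 - v, t)
        return u - b._cdf(u, 1 - v, t)

    def _hu(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return b._hu(1 - u, v, t)
        if self.rotation == 180:
            return 1.0 - b._hu(1 - u, 1 - v, t)
        return 1.0 - b._hu(u, 1 - v, t)

    def _hv(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return 1.0 - b._hv(1 - u, v, t)
        if self.rotation == 180:
            return 1.0 - b._hv(1 - u, 1 - v, t)
        return b._hv(u, 1 - v, t)

    def _dhv_du(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return b._dhv_du(1 - u, v, t)
        if self.rotation == 180:
            return b._dhv_du(1 - u, 1 - v, t)
        return b._dhv_du(u, 1 - v, t)

    def _dhv_dv(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return -b._dhv_dv(1 - u, v, t)
        if self.rotation == 180:
            return b._dhv_dv(1 - u, 1 - v, t)
        return -b._dhv_dv(u, 1 - v, t)

    def _dhv_dt(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return -b._dhv_dt(1 - u, v, t)
        if self.rotation == 180:
            return -b._dhv_dt(1 - u, 1 - v, t)
        return b._dhv_dt(u, 1 - v, t)

    def _dcdf_dt(self, u, v, t):
        b = self.base
        if self.rotation == 90:
            return -b._dcdf_dt(1 - u, v, t)
        if self.rotation == 180:
            return b._dcdf_dt(1 - u, 1 - v, t)
        return -b._dcdf_dt(u, 1 - v, t)

    def _tau(self, t):
        sgn = -1.0 if self.rotation in (90, 270) else 1.0
        return sgn * self.base._tau(t)

    def __repr__(self):  # pragma: no cover
        return f"<copula {self.name}{self.rotation}>"


COPULA_FAMILIES = {
    "gaussian": GaussianCopula,
    "clayton": ClaytonCopula,
    "gumbel": GumbelCopula,
    "frank": FrankCopula,
    "fgm": FGMCopula,
    "amh": AMHCopula,
}


def get_copula(name: str) -> Copula:
    """Build a copula from a config string, e.g. ``"clayton"`` or
    ``"clayton270"`` (base family plus rotation angle)."""
    key = name.strip().lower()
    rotation = 0
    for ang in (270, 180, 90):
        if key.endswith(str(ang)):
            rotation = ang
            key = key[: -len(str(ang))]
            break
    if key not in COPULA_FAMILIES:
        raise ValueError(f"unknown copula family '{name}'; known: {sorted(COPULA_FAMILIES)}")
    cop = COPULA_FAMILIES[key]()
    if rotation:
        cop = cop.rotate(rotation)
    return cop
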