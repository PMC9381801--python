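"""Bivariate copula families with h-functions and maximum-likelihood fitting.

Implements the competing families used per spatial bin — Gaussian,
Student-t, Clayton, Frank, Gumbel, Joe — plus the independence copula
``Π(u,v) = uv`` (large-distance limit) and the comonotonic copula
``M(u,v) = min(u,v)`` (zero-distance limit). Each family exposes

* ``cdf``  — the copula ``C(u, v)``,
* ``pdf``  — its density ``c(u, v) = ∂²C/∂u∂v``,
* ``hfunc`` — the conditional CDF ``h(u|v) = ∂C(u,v)/∂v = P[U ≤ u | V = v]``,
* ``hinv`` — the inverse of ``hfunc`` in its first argument,

all vectorised over NumPy arrays. Rotations by 90/180/270 degrees are
supported through the standard reflection identities, which is how the
single-parameter positive-dependence families (Clayton/Gumbel/Joe) handle
negatively dependent bins. Kendall-tau <-> parameter maps provide fitting
ranges and sanity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

from .errors import FitError, ParameterError, SupportError, UnsupportedOperationError

__all__ = [
    "CopulaModel",
    "COPULA_FAMILIES",
    "copula_cdf",
    "copula_pdf",
    "hfunc",
    "hinv",
    "tau_from_theta",
    "theta_from_tau",
    "fit_copula_ml",
    "select_copula",
    "sample_copula",
]

log = logging.getLogger(__name__)

_EPS = 1e-12
#: interior clip used before evaluating densities/h-functions
_IN = 1e-9

#: registry order fixes log-likelihood tie-breaks in selection
COPULA_FAMILIES: tuple[str, ...] = (
    "gaussian", "student_t", "clayton", "frank", "gumbel", "joe",
    "independence", "comonotonic",
)

_ARCHIMEDEAN_POSITIVE = frozenset({"clayton", "gumbel", "joe"})

# admissible parameter ranges used for bounded ML optimisation
_THETA_BOUNDS = {
    "gaussian": (-0.9999, 0.9999),
    "student_t": (-0.9999, 0.9999),  # correlation; df profiled on a grid
    "clayton": (1e-3, 30.0),
    "frank": (1e-4, 35.0),  # magnitude; sign from the sample tau
    "gumbel": (1.0, 50.0),
    "joe": (1.0, 50.0),
}

_T_DF_GRID = tuple(range(2, 31))

# 64-node Gauss-Legendre rule on [0, 1], used for the Student-t copula CDF
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0


def _clip(u):
    return np.clip(np.asarray(u, dtype=float), _IN, 1.0 - _IN)


# ---------------------------------------------------------------------------
# family implementations (unrotated); theta is a tuple
# ---------------------------------------------------------------------------


class _Independence:
    @staticmethod
    def check(theta):
        if theta:
            raise ParameterError("independence copula takes no parameter")

    @staticmethod
    def cdf(u, v, theta):
        return np.asarray(u) * np.asarray(v)

    @staticmethod
    def pdf(u, v, theta):
        return np.ones(np.broadcast(np.asarray(u), np.asarray(v)).shape)

    @staticmethod
    def hfunc(u, v, theta):
        return np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v))[0].copy()

    @staticmethod
    def hinv(t, v, theta):
        return np.broadcast_arrays(np.asarray(t, dtype=float), np.asarray(v))[0].copy()

    @staticmethod
    def tau(theta):
        return 0.0


class _Comonotonic:
    """Perfect positive dependence M(u,v) = min(u,v): the h -> 0 limit.

    Its conditional distribution is a step function, so density and
    h-function are not defined as ordinary functions; it is exposed for the
    limit statement only and never fitted.
    """

    @staticmethod
    def check(theta):
        if theta:
            raise ParameterError("comonotonic copula takes no parameter")

    @staticmethod
    def cdf(u, v, theta):
        return np.minimum(np.asarray(u, dtype=float), np.asarray(v, dtype=float))

    @staticmethod
    def pdf(u, v, theta):
        raise UnsupportedOperationError("comonotonic copula has no density")

    @staticmethod
    def hfunc(u, v, theta):
        raise UnsupportedOperationError(
            "comonotonic h-function is a step (distributional derivative)"
        )

    hinv = hfunc

    @staticmethod
    def tau(theta):
        return 1.0


class _Gaussian:
    @staticmethod
    def check(theta):
        (rho,) = theta
        if not -1.0 < rho < 1.0:
            raise ParameterError(f"gaussian correlation must be in (-1,1), got {rho}")

    @staticmethod
    def cdf(u, v, theta):
        (rho,) = theta
        u, v = _clip(u), _clip(v)
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1)
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        return np.asarray(mvn.cdf(pts))

    @staticmethod
    def pdf(u, v, theta):
        (rho,) = theta
        u, v = _clip(u), _clip(v)
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        r2 = 1.0 - rho * rho
        expo = -(rho * rho * (x * x + y * y) - 2.0 * rho * x * y) / (2.0 * r2)
        return np.exp(expo) / np.sqrt(r2)

    @staticmethod
    def hfunc(u, v, theta):
        (rho,) = theta
        u, v = _clip(u), _clip(v)
        x, y = stats.norm.ppf(u), stats.norm.ppf(v)
        return stats.norm.cdf((x - rho * y) / np.sqrt(1.0 - rho * rho))

    @staticmethod
    def hinv(t, v, theta):
        (rho,) = theta
        t, v = _clip(t), _clip(v)
        y = stats.norm.ppf(v)
        x = stats.norm.ppf(t) * np.sqrt(1.0 - rho * rho) + rho * y
        return stats.norm.cdf(x)

    @staticmethod
    def tau(theta):
        return 2.0 / np.pi * np.arcsin(theta[0])


class _StudentT:
    @staticmethod
    def check(theta):
        rho, df = theta
        if not -1.0 < rho < 1.0:
            raise ParameterError(f"t correlation must be in (-1,1), got {rho}")
        if df <= 0:
            raise ParameterError(f"t degrees of freedom must be positive, got {df}")

    @staticmethod
    def hfunc(u, v, theta):
        rho, df = theta
        u, v = _clip(u), _clip(v)
        x, y = stats.t.ppf(u, df), stats.t.ppf(v, df)
        scale = np.sqrt((df + y * y) * (1.0 - rho * rho) / (df + 1.0))
        return stats.t.cdf((x - rho * y) / scale, df + 1.0)

    @staticmethod
    def hinv(t, v, theta):
        rho, df = theta
        t, v = _clip(t), _clip(v)
        y = stats.t.ppf(v, df)
        scale = np.sqrt((df + y * y) * (1.0 - rho * rho) / (df + 1.0))
        x = stats.t.ppf(t, df + 1.0) * scale + rho * y
        return stats.t.cdf(x, df)

    @staticmethod
    def cdf(u, v, theta):
        # C(u, v) = ∫_0^v h(u | w) dw, by fixed Gauss-Legendre quadrature
        # (deterministic, unlike randomised-QMC multivariate integration)
        u = _clip(u)
        v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
        u_b, v_b = np.broadcast_arrays(u, v)
        w = v_b[..., None] * _GL_X  # nodes on [0, v]
        h = _StudentT.hfunc(u_b[..., None], w, theta)
        return np.einsum("...k,k->...", h, _GL_W) * v_b

    @staticmethod
    def pdf(u, v, theta):
        rho, df = theta
        u, v = _clip(u), _clip(v)
        x, y = stats.t.ppf(u, df), stats.t.ppf(v, df)
        r2 = 1.0 - rho * rho
        q = (x * x - 2.0 * rho * x * y + y * y) / (df * r2)
        log_num = (
            special.gammaln((df + 2.0) / 2.0)
            + special.gammaln(df / 2.0)
            - 2.0 * special.gammaln((df + 1.0) / 2.0)
            - 0.5 * np.log(r2)
            - (df + 2.0) / 2.0 * np.log1p(q)
        )
        log_den = (
            -(df + 1.0) / 2.0 * (np.log1p(x * x / df) + np.log1p(y * y / df))
        )
        return np.exp(log_num - log_den)

    @staticmethod
    def tau(theta):
        return 2.0 / np.pi * np.arcsin(theta[0])


class _Clayton:
    @staticmethod
    def check(theta):
        (th,) = theta
        if th <= 0:
            raise ParameterError(f"clayton parameter must be positive, got {th}")

    @staticmethod
    def cdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        base = u ** (-th) + v ** (-th) - 1.0
        return base ** (-1.0 / th)

    @staticmethod
    def pdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        base = u ** (-th) + v ** (-th) - 1.0
        return (1.0 + th) * (u * v) ** (-th - 1.0) * base ** (-2.0 - 1.0 / th)

    @staticmethod
    def hfunc(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        base = u ** (-th) + v ** (-th) - 1.0
        return v ** (-th - 1.0) * base ** (-1.0 - 1.0 / th)

    @staticmethod
    def hinv(t, v, theta):
        (th,) = theta
        t, v = _clip(t), _clip(v)
        inner = (t * v ** (th + 1.0)) ** (-th / (th + 1.0)) + 1.0 - v ** (-th)
        return np.clip(inner, _EPS, None) ** (-1.0 / th)

    @staticmethod
    def tau(theta):
        th = theta[0]
        return th / (th + 2.0)


class _Frank:
    @staticmethod
    def check(theta):
        (th,) = theta
        if th == 0.0:
            raise ParameterError("frank parameter must be non-zero")

    @staticmethod
    def _abd(u, v, th):
        return np.expm1(-th * u), np.expm1(-th * v), np.expm1(-th)

    @staticmethod
    def cdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        a, b, d = _Frank._abd(u, v, th)
        return -np.log1p(a * b / d) / th

    @staticmethod
    def pdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        a, b, d = _Frank._abd(u, v, th)
        return -th * d * np.exp(-th * (u + v)) / (d + a * b) ** 2

    @staticmethod
    def hfunc(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        a, b, d = _Frank._abd(u, v, th)
        return a * np.exp(-th * v) / (d + a * b)

    @staticmethod
    def hinv(t, v, theta):
        (th,) = theta
        t, v = _clip(t), _clip(v)
        b = np.expm1(-th * v)
        d = np.expm1(-th)
        a = t * d / (np.exp(-th * v) - t * b)
        return np.clip(-np.log1p(a) / th, 0.0, 1.0)

    @staticmethod
    def tau(theta):
        th = theta[0]
        if th < 0:
            return -_Frank.tau((-th,))
        debye1 = integrate.quad(lambda t: t / np.expm1(t), 0.0, th)[0] / th
        return 1.0 - 4.0 / th * (1.0 - debye1)


class _Gumbel:
    @staticmethod
    def check(theta):
        (th,) = theta
        if th < 1.0:
            raise ParameterError(f"gumbel parameter must be >= 1, got {th}")

    @staticmethod
    def cdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        lu, lv = -np.log(u), -np.log(v)
        return np.exp(-((lu ** th + lv ** th) ** (1.0 / th)))

    @staticmethod
    def pdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        lu, lv = -np.log(u), -np.log(v)
        s = lu ** th + lv ** th
        w = s ** (1.0 / th)
        return (
            np.exp(-w) / (u * v) * (lu * lv) ** (th - 1.0)
            * w ** (2.0 - 2.0 * th) * (1.0 + (th - 1.0) / w)
        )

    @staticmethod
    def hfunc(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        lu, lv = -np.log(u), -np.log(v)
        w = (lu ** th + lv ** th) ** (1.0 / th)
        return np.exp(-w) * lv ** (th - 1.0) * w ** (1.0 - th) / v

    @staticmethod
    def hinv(t, v, theta):
        return _bisect_hinv(_Gumbel.hfunc, t, v, theta)

    @staticmethod
    def tau(theta):
        return 1.0 - 1.0 / theta[0]


class _Joe:
    @staticmethod
    def check(theta):
        (th,) = theta
        if th < 1.0:
            raise ParameterError(f"joe parameter must be >= 1, got {th}")

    @staticmethod
    def cdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        x, y = (1.0 - u) ** th, (1.0 - v) ** th
        return 1.0 - (x + y - x * y) ** (1.0 / th)

    @staticmethod
    def pdf(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        x, y = (1.0 - u) ** th, (1.0 - v) ** th
        s = x + y - x * y
        return (
            (1.0 - u) ** (th - 1.0) * (1.0 - v) ** (th - 1.0)
            * s ** (1.0 / th - 2.0) * (th - 1.0 + s)
        )

    @staticmethod
    def hfunc(u, v, theta):
        (th,) = theta
        u, v = _clip(u), _clip(v)
        x, y = (1.0 - u) ** th, (1.0 - v) ** th
        s = x + y - x * y
        return (1.0 - v) ** (th - 1.0) * (1.0 - x) * s ** (1.0 / th - 1.0)

    @staticmethod
    def hinv(t, v, theta):
        return _bisect_hinv(_Joe.hfunc, t, v, theta)

    @staticmethod
    def tau(theta):
        (th,) = theta
        if th == 1.0:
            return 0.0

        # Archimedean relation: tau = 1 + 4 ∫ φ(t)/φ'(t) dt with the Joe
        # generator φ(t) = -log(1 - (1-t)^θ); substituting s = 1 - t,
        # φ/φ' = g log(g) s^(1-θ) / θ with g = 1 - s^θ, which tends to
        # -s/θ as s -> 0 (guarded to avoid 0 * inf)
        def integrand(s):
            p = s ** th
            if p < 1e-12:
                return -s / th
            g = 1.0 - p
            return g * np.log1p(-p) * s ** (1.0 - th) / th

        val = integrate.quad(integrand, 0.0, 1.0, limit=200)[0]
        return 1.0 + 4.0 * val


def _bisect_hinv(hf, t, v, theta, iters: int = 60):
    """Vectorised bisection for h-function inverses with no closed form.

    ``hfunc`` is nondecreasing in u with range [0, 1], so a root always
    exists; 60 halvings bound the u-error by 2^-60 << 1e-9.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    t_b, v_b = np.broadcast_arrays(t, v)
    lo = np.full(t_b.shape, _EPS)
    hi = np.full(t_b.shape, 1.0 - _EPS)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        high = hf(mid, v_b, theta) > t_b
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


_IMPL = {
    "independence": _Independence,
    "comonotonic": _Comonotonic,
    "gaussian": _Gaussian,
    "student_t": _StudentT,
    "clayton": _Clayton,
    "frank": _Frank,
    "gumbel": _Gumbel,
    "joe": _Joe,
}


# ---------------------------------------------------------------------------
# model object with rotations
# ---------------------------------------------------------------------------


@dataclass
class CopulaModel:
    """A parametrised (possibly rotated) bivariate copula.

    ``rotation`` applies the standard reflection identities: 180 degrees is
    the survival copula; 90/270 reflect one margin and flip the sign of the
    dependence, which lets the positive-dependence Archimedean families
    model negatively dependent bins.
    """

    family: str
    theta: tuple[float, ...] = ()
    rotation: int = 0
    loglik: float | None = None
    candidate_logliks: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _IMPL:
            raise ParameterError(f"unknown copula family {self.family!r}")
        if self.rotation not in (0, 90, 180, 270):
            raise ParameterError("rotation must be one of 0, 90, 180, 270")
        self.theta = tuple(float(t) for t in self.theta)
        _IMPL[self.family].check(self.theta)

    # -- evaluations, rotation-aware ---------------------------------------

    def cdf(self, u, v):
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
        impl = _IMPL[self.family]
        if self.rotation == 0:
            res = impl.cdf(u, v, self.theta)
        elif self.rotation == 90:
            res = v - impl.cdf(1.0 - u, v, self.theta)
        elif self.rotation == 180:
            res = u + v - 1.0 + impl.cdf(1.0 - u, 1.0 - v, self.theta)
        else:
            res = u - impl.cdf(u, 1.0 - v, self.theta)
        # uniform margins hold exactly on the boundary of the unit square
        res = np.where(v >= 1.0, u, np.where(u >= 1.0, v, res))
        return np.where((u <= 0.0) | (v <= 0.0), 0.0, res)

    def pdf(self, u, v):
        impl = _IMPL[self.family]
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.rotation == 0:
            return impl.pdf(u, v, self.theta)
        if self.rotation == 90:
            return impl.pdf(1.0 - u, v, self.theta)
        if self.rotation == 180:
            return impl.pdf(1.0 - u, 1.0 - v, self.theta)
        return impl.pdf(u, 1.0 - v, self.theta)

    def hfunc(self, u, v):
        """Conditional CDF ``P[U <= u | V = v] = ∂C/∂v``."""
        impl = _IMPL[self.family]
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.rotation == 0:
            res = impl.hfunc(u, v, self.theta)
        elif self.rotation == 90:
            res = 1.0 - impl.hfunc(1.0 - u, v, self.theta)
        elif self.rotation == 180:
            res = 1.0 - impl.hfunc(1.0 - u, 1.0 - v, self.theta)
        else:
            res = impl.hfunc(u, 1.0 - v, self.theta)
        # h(0|v) = 0 and h(1|v) = 1 hold exactly
        return np.where(u <= 0.0, 0.0, np.where(u >= 1.0, 1.0, res))

    def hinv(self, t, v):
        """Solve ``hfunc(u | v) = t`` for u."""
        impl = _IMPL[self.family]
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if self.rotation == 0:
            return impl.hinv(t, v, self.theta)
        if self.rotation == 90:
            return 1.0 - impl.hinv(1.0 - t, v, self.theta)
        if self.rotation == 180:
            return 1.0 - impl.hinv(1.0 - t, 1.0 - v, self.theta)
        return impl.hinv(t, 1.0 - v, self.theta)

    def tau(self) -> float:
        base = _IMPL[self.family].tau(self.theta)
        return -base if self.rotation in (90, 270) else base


# module-level functional forms mirroring the operation contracts
def copula_cdf(model: CopulaModel, u, v):
    return model.cdf(u, v)


def copula_pdf(model: CopulaModel, u, v):
    return model.pdf(u, v)


def hfunc(model: CopulaModel, u, v):
    return model.hfunc(u, v)


def hinv(model: CopulaModel, t, v):
    return model.hinv(t, v)


# ---------------------------------------------------------------------------
# tau <-> theta maps
# ---------------------------------------------------------------------------


def tau_from_theta(family: str, theta) -> float:
    if family not in _IMPL:
        raise ParameterError(f"unknown copula family {family!r}")
    theta = tuple(np.atleast_1d(theta).astype(float)) if not isinstance(theta, tuple) else theta
    _IMPL[family].check(theta)
    return float(_IMPL[family].tau(theta))


def theta_from_tau(family: str, tau: float) -> tuple[float, ...]:
    """Parameter whose Kendall tau equals ``tau`` (closed form where it
    exists, otherwise numeric inversion). Raises for unattainable taus,
    suggesting a rotation for the positive-dependence families."""
    tau = float(tau)
    if not -1.0 < tau < 1.0:
        raise SupportError("tau must lie in (-1, 1)")
    if family == "gaussian":
        return (float(np.sin(np.pi * tau / 2.0)),)
    if family == "student_t":
        return (float(np.sin(np.pi * tau / 2.0)), 4.0)
    if family in _ARCHIMEDEAN_POSITIVE and tau < 0:
        raise SupportError(
            f"{family} cannot attain negative tau; fit its 90/270-degree rotation"
        )
    if family == "clayton":
        if tau <= 0:
            raise SupportError("clayton requires tau > 0 (or a rotation)")
        return (2.0 * tau / (1.0 - tau),)
    if family == "gumbel":
        return (1.0 / (1.0 - tau),)
    if family == "joe":
        if tau == 0.0:
            return (1.0,)
        sol = optimize.brentq(lambda th: _Joe.tau((th,)) - tau, 1.0 + 1e-9, 500.0)
        return (float(sol),)
    if family == "frank":
        if tau == 0.0:
            raise SupportError("frank is undefined at exact independence (theta=0)")
        mag = optimize.brentq(lambda th: _Frank.tau((th,)) - abs(tau), 1e-8, 500.0)
        return (float(np.sign(tau) * mag),)
    if family == "independence":
        if tau != 0.0:
            raise SupportError("independence copula has tau = 0")
        return ()
    raise SupportError(f"no tau inversion for family {family!r}")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _neg_loglik(impl, theta, u, v):
    with np.errstate(all="ignore"):
        dens = impl.pdf(u, v, theta)
        ll = np.log(np.clip(dens, 1e-300, None)).sum()
    return -ll if np.isfinite(ll) else np.inf


def fit_copula_ml(u, v, family: str, rotation: int | None = None) -> CopulaModel:
    """Fit one family by maximum likelihood on pseudo-observations.

    The pair set is symmetrised — spatial dependence between the two ends
    of a location pair has no natural orientation, so each (u, v) also
    enters as (v, u); the reported log-likelihood is the symmetrised sum
    divided by two. For Clayton/Gumbel/Joe a negative sample tau triggers
    the 90-degree rotation automatically (recorded on the model). The
    sample tau restricts Frank to the matching sign and seeds the bounded
    optimiser's admissible interval.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size or u.size < 10:
        raise SupportError("need at least 10 (u, v) pairs")
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise SupportError("pseudo-observations must lie strictly inside (0, 1)")
    if family not in _IMPL or family == "comonotonic":
        raise SupportError(f"family {family!r} cannot be fitted")

    n = u.size
    us = np.concatenate([u, v])
    vs = np.concatenate([v, u])

    if family == "independence":
        return CopulaModel("independence", (), 0, loglik=0.0)

    tau_s = stats.kendalltau(u, v).statistic
    if rotation is None:
        rotation = 90 if (family in _ARCHIMEDEAN_POSITIVE and tau_s < 0) else 0
        if rotation:
            log.info("negative sample tau %.3f: fitting %s rotated 90 degrees", tau_s, family)
    # reduce the rotated problem to the base family on reflected data
    if rotation == 90:
        uf, vf = 1.0 - us, vs
    elif rotation == 180:
        uf, vf = 1.0 - us, 1.0 - vs
    elif rotation == 270:
        uf, vf = us, 1.0 - vs
    else:
        uf, vf = us, vs

    impl = _IMPL[family]
    lo, hi = _THETA_BOUNDS[family]

    if family == "student_t":
        best = None
        for df in _T_DF_GRID:
            res = optimize.minimize_scalar(
                lambda r, d=df: _neg_loglik(impl, (r, d), uf, vf),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            if best is None or res.fun < best[0]:
                best = (res.fun, (float(res.x), float(df)))
        if best is None or not np.isfinite(best[0]):
            raise FitError("student_t profile fit failed")
        nll, theta = best
    else:
        if family == "frank":
            bounds = (lo, hi) if tau_s >= 0 else (-hi, -lo)
        else:
            bounds = (lo, hi)
        res = optimize.minimize_scalar(
            lambda th: _neg_loglik(impl, (th,), uf, vf),
            bounds=bounds, method="bounded", options={"xatol": 1e-8},
        )
        if not np.isfinite(res.fun):
            raise FitError(f"ML fit failed for family {family!r}")
        nll, theta = res.fun, (float(res.x),)

    return CopulaModel(family, theta, rotation, loglik=float(-nll / 2.0))


def select_copula(u, v, families=("gaussian", "clayton", "frank", "gumbel", "joe"),
                  criterion: str = "loglik") -> CopulaModel:
    """Fit every candidate family and keep the best by raw log-likelihood
    (the default, matching standard practice) or by AIC
    (``criterion='aic'``, which penalises Student-t's second parameter);
    ties break by registry order. Candidates' log-likelihoods are
    retained on the winner."""
    families = list(families)
    if not families:
        raise SupportError("empty candidate family list")
    if criterion not in ("loglik", "aic"):
        raise SupportError("criterion must be 'loglik' or 'aic'")
    ordered = [f for f in COPULA_FAMILIES if f in families]
    ordered += [f for f in families if f not in COPULA_FAMILIES]
    fits: dict[str, CopulaModel] = {}
    failures: dict[str, str] = {}
    for fam in ordered:
        try:
            fits[fam] = fit_copula_ml(u, v, fam)
        except (SupportError, FitError, ParameterError) as exc:
            failures[fam] = str(exc)
            log.warning("copula fit failed for %s: %s", fam, exc)
    if not fits:
        raise FitError(f"all copula candidates failed: {failures}")
    if criterion == "aic":
        score = lambda c: c.loglik - len(c.theta)  # -AIC/2 up to a constant
    else:
        score = lambda c: c.loglik
    best = max(fits.values(), key=score)
    best.candidate_logliks = {f: c.loglik for f, c in fits.items()}
    return best


def sample_copula(model: CopulaModel, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` pairs by conditional inversion: ``v, w ~ U(0,1)`` i.i.d.,
    ``u = hinv(w | v)``. Returns an (n, 2) array."""
    if n < 1:
        raise SupportError("n must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.random(n)
    w = rng.random(n)
    if model.family == "comonotonic":
        u = v.copy()
    else:
        u = np.asarray(model.hinv(w, v), dtype=float)
    return np.column_stack([u, v])
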