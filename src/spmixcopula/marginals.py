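"""Parametric marginal models for the spatial variables.

Each variable is assumed second-order stationary, so a single marginal CDF
``F_l`` is fitted from all ``n`` observations of variable ``l``. Candidate
families are Gamma, Weibull, Normal and Log-normal (all two-parameter, so
raw maximum log-likelihood is a fair selection criterion); the registry is
extensible. Fitted CDFs turn raw observations into pseudo-observations in
``(0, 1)`` for copula estimation, and their inverses map conditional
quantiles back to the data scale at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, SupportError

__all__ = [
    "MarginalModel",
    "fit_marginal",
    "select_marginal",
    "marginal_transform",
    "MARGINAL_FAMILIES",
]

log = logging.getLogger(__name__)

#: clip level for CDF outputs entering copula likelihoods
CDF_EPS = 1e-10

_POSITIVE_SUPPORT = frozenset({"gamma", "weibull", "lognormal"})

#: registry order fixes log-likelihood tie-breaks
MARGINAL_FAMILIES: tuple[str, ...] = ("gamma", "weibull", "normal", "lognormal")


def _frozen(family: str, params: dict[str, float]):
    if family == "gamma":
        return stats.gamma(params["shape"], loc=0.0, scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(params["shape"], loc=0.0, scale=params["scale"])
    if family == "normal":
        return stats.norm(loc=params["mean"], scale=params["sd"])
    if family == "lognormal":
        return stats.lognorm(params["sigma"], loc=0.0, scale=np.exp(params["mu"]))
    raise SupportError(f"unknown marginal family {family!r}")


@dataclass
class MarginalModel:
    """A fitted parametric marginal CDF ``F_l``.

    ``params`` are the family's natural parameters (all scale/shape
    parameters positive); ``loglik`` is the summed log-density at the data
    used for the fit and is recomputable from ``params``.
    """

    family: str
    params: dict[str, float]
    loglik: float
    n: int
    candidate_logliks: dict[str, float] = field(default_factory=dict)

    def _dist(self):
        return _frozen(self.family, self.params)

    def cdf(self, z) -> np.ndarray:
        return self._dist().cdf(z)

    def pdf(self, z) -> np.ndarray:
        return self._dist().pdf(z)

    def logpdf(self, z) -> np.ndarray:
        return self._dist().logpdf(z)

    def quantile(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise SupportError("quantile inputs must lie strictly inside (0, 1)")
        return self._dist().ppf(p)

    def median(self) -> float:
        return float(self._dist().median())

    def support(self) -> tuple[float, float]:
        return tuple(map(float, self._dist().support()))


def _check_support(values: np.ndarray, family: str) -> None:
    if family in _POSITIVE_SUPPORT and np.any(values <= 0.0):
        raise SupportError(
            f"family {family!r} requires strictly positive values; "
            f"min observed {values.min():g}"
        )


def fit_marginal(values, family: str) -> MarginalModel:
    """Maximum-likelihood fit of one candidate family.

    Gamma/Weibull/Log-normal are fitted with the location fixed at zero
    (two free parameters each); the Normal MLE is closed form with the
    population standard deviation.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3 or not np.all(np.isfinite(values)):
        raise SupportError("need at least 3 finite values")
    if family not in MARGINAL_FAMILIES:
        raise SupportError(f"unknown marginal family {family!r}")
    _check_support(values, family)
    if np.ptp(values) == 0.0:
        raise FitError(f"degenerate (zero-variance) sample for family {family!r}")

    try:
        if family == "gamma":
            a, _, scale = stats.gamma.fit(values, floc=0.0)
            params = {"shape": float(a), "scale": float(scale)}
        elif family == "weibull":
            c, _, scale = stats.weibull_min.fit(values, floc=0.0)
            params = {"shape": float(c), "scale": float(scale)}
        elif family == "normal":
            params = {"mean": float(values.mean()), "sd": float(values.std())}
        else:  # lognormal: closed-form MLE on log scale
            logs = np.log(values)
            params = {"mu": float(logs.mean()), "sigma": float(logs.std())}
    except Exception as exc:  # scipy raises plain exceptions on failure
        raise FitError(f"MLE for family {family!r} failed: {exc}") from exc

    loglik = float(_frozen(family, params).logpdf(values).sum())
    if not np.isfinite(loglik):
        raise FitError(f"non-finite log-likelihood for family {family!r}")
    return MarginalModel(family=family, params=params, loglik=loglik, n=values.size)


def select_marginal(values, families=MARGINAL_FAMILIES) -> MarginalModel:
    """Fit every candidate family and keep the one with the largest
    log-likelihood; ties break by registry order. All candidates'
    log-likelihoods are retained on the winner for reporting."""
    families = list(families)
    if not families:
        raise SupportError("empty candidate family list")
    # evaluate in registry order so ties resolve deterministically
    ordered = [f for f in MARGINAL_FAMILIES if f in families]
    ordered += [f for f in families if f not in MARGINAL_FAMILIES]
    fits: dict[str, MarginalModel] = {}
    failures: dict[str, str] = {}
    for fam in ordered:
        try:
            fits[fam] = fit_marginal(values, fam)
        except (SupportError, FitError) as exc:
            failures[fam] = str(exc)
            log.warning("marginal fit failed for %s: %s", fam, exc)
    if not fits:
        raise FitError(f"all marginal candidates failed: {failures}")
    best = max(fits.values(), key=lambda m: m.loglik)  # max keeps first on ties
    best.candidate_logliks = {f: m.loglik for f, m in fits.items()}
    return best


def marginal_transform(model: MarginalModel, values, direction: str = "cdf"):
    """Push data through ``F_l`` (``direction='cdf'``, output clipped into
    ``[1e-10, 1-1e-10]`` so copula log-densities stay finite) or pull
    probabilities back through ``F_l^{-1}`` (``direction='quantile'``)."""
    values = np.asarray(values, dtype=float)
    if direction == "cdf":
        return np.clip(model.cdf(values), CDF_EPS, 1.0 - CDF_EPS)
    if direction == "quantile":
        return model.quantile(values)
    raise SupportError(f"direction must be 'cdf' or 'quantile', got {direction!r}")
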