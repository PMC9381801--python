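"""Spatial mixture copulas: per-bin cross-variable mixtures glued across
distance bins by distance-dependent convex weights.

Within each distance bin ``k`` the ``m`` variables' fitted spatial copulas
are combined as ``C^m_k(u,v) = Σ_l w_l C_{l,k}(u,v)`` with mixture weights
``w_l`` summing to one (equal weights by default). Across bins the model
is a piecewise convex combination: for a separation ``h`` in bin ``k`` the
copula is ``(1-λ_k) C^m_{k-1} + λ_k C^m_k``, where
``λ_k = (h̄_k − h_{k-1}) / (h_k − h_{k-1})`` places the bin's mean pair
distance within the bin. Below the first bin edge the first bin's mixture
is used alone; at or beyond the cut-off the model is exactly the product
copula ``uv`` (independence). Every piece is a convex combination of
copulas and hence itself a copula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction

import numpy as np

from .dataset import SpatialDataset
from .errors import FitError, SupportError
from .families import CopulaModel, fit_copula_ml, select_copula
from .geometry import (
    BinningScheme,
    bin_pairs,
    empirical_correlogram,
    pairwise_distances,
    select_cutoff,
)
from .marginals import MARGINAL_FAMILIES, MarginalModel, marginal_transform, select_marginal

__all__ = [
    "MixtureCopula",
    "SpatialMixtureCopula",
    "FitConfig",
    "build_bin_mixture",
    "lambda_weights",
    "format_lambda",
    "spatial_mixture_cdf",
    "spatial_mixture_hfunc",
    "spatial_mixture_hinv",
    "fit_spatial_mixture",
    "optimize_weights",
]

log = logging.getLogger(__name__)

_WEIGHT_TOL = 1e-12


@dataclass
class MixtureCopula:
    """Convex combination of one fitted copula per variable (one bin)."""

    components: list[CopulaModel]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.components) != self.weights.size or not len(self.components):
            raise SupportError("one weight per component required")
        if np.any(self.weights <= 0.0) or np.any(self.weights > 1.0):
            raise SupportError("mixture weights must lie in (0, 1]")
        if abs(self.weights.sum() - 1.0) > _WEIGHT_TOL:
            raise SupportError(f"mixture weights must sum to 1, got {self.weights.sum()!r}")

    def cdf(self, u, v):
        return sum(w * c.cdf(u, v) for w, c in zip(self.weights, self.components))

    def pdf(self, u, v):
        return sum(w * c.pdf(u, v) for w, c in zip(self.weights, self.components))

    def hfunc(self, u, v):
        # the derivative of a convex combination is the same combination
        # of derivatives
        return sum(w * c.hfunc(u, v) for w, c in zip(self.weights, self.components))


def build_bin_mixture(components, weights) -> MixtureCopula:
    """Assemble one bin's cross-variable mixture ``Σ_l w_l C_l``."""
    return MixtureCopula(list(components), np.asarray(weights, dtype=float))


def lambda_weights(binning: BinningScheme) -> list[Fraction]:
    """Distance-dependent blending weights ``λ_k`` for bins ``k = 2..K``.

    ``λ_k = (h̄_k − h_{k-1}) / (h_k − h_{k-1})`` is kept as an exact
    Fraction of the stored mean distance; an empty bin has no mean and
    falls back to the bin midpoint (λ = 1/2), with a warning.
    """
    out: list[Fraction] = []
    for k in range(2, binning.n_bins + 1):
        lo = Fraction(binning.edges[k - 1]).limit_denominator(10**12)
        hi = Fraction(binning.edges[k]).limit_denominator(10**12)
        mean = binning.mean_distances[k - 1]
        if not np.isfinite(mean):
            log.warning("bin %d empty: lambda defaults to the midpoint 1/2", k)
            out.append(Fraction(1, 2))
            continue
        lam = (Fraction(float(mean)) - lo) / (hi - lo)
        if not 0 <= lam <= 1:
            raise SupportError(f"bin {k} mean distance outside its edges")
        out.append(lam)
    return out


def format_lambda(lam: Fraction, digits: int = 2) -> str:
    """Display rounding, half away from zero (0.575 renders as '0.58')."""
    with localcontext() as ctx:
        ctx.prec = 40
        d = Decimal(lam.numerator) / Decimal(lam.denominator)
        return str(d.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


@dataclass
class SpatialMixtureCopula:
    """The fitted distance-dependent mixture copula plus its marginals."""

    binning: BinningScheme
    bin_mixtures: list[MixtureCopula]
    lambdas: list[Fraction]
    marginals: list[MarginalModel]
    weights: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bin_mixtures) != self.binning.n_bins:
            raise SupportError("one mixture per bin required")
        if len(self.lambdas) != max(self.binning.n_bins - 1, 0):
            raise SupportError("need lambdas for bins 2..K")

    @property
    def m(self) -> int:
        return len(self.marginals)

    def _pieces(self, h: float):
        """Return [(coef, mixture), ...] active at separation h, or None in
        the independence region h >= cutoff."""
        k = self.binning.bin_of(float(h))
        if k is None:
            return None
        if k == 1:
            return [(1.0, self.bin_mixtures[0])]
        lam = float(self.lambdas[k - 2])
        return [(1.0 - lam, self.bin_mixtures[k - 2]), (lam, self.bin_mixtures[k - 1])]

    def cdf(self, u, v, h: float):
        pieces = self._pieces(h)
        if pieces is None:
            return np.asarray(u, dtype=float) * np.asarray(v, dtype=float)
        return sum(c * mix.cdf(u, v) for c, mix in pieces)

    def hfunc(self, u, v, h: float):
        """Conditional CDF ``∂C^m_h/∂v (u, v) = P[U <= u | V = v]``."""
        pieces = self._pieces(h)
        if pieces is None:
            return np.broadcast_arrays(np.asarray(u, dtype=float), np.asarray(v))[0].copy()
        return sum(c * mix.hfunc(u, v) for c, mix in pieces)

    def hinv(self, t, v, h: float, iters: int = 60):
        """Solve ``hfunc(u, v, h) = t`` for u by vectorised bisection
        (monotone in u; 60 halvings give u-error < 1e-18)."""
        pieces = self._pieces(h)
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if pieces is None:
            return np.broadcast_arrays(t, v)[0].copy()
        t_b, v_b = np.broadcast_arrays(t, v)
        lo = np.zeros(t_b.shape)
        hi = np.ones(t_b.shape)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            high = sum(c * mix.hfunc(mid, v_b) for c, mix in pieces) > t_b
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        return 0.5 * (lo + hi)


def spatial_mixture_cdf(model: SpatialMixtureCopula, u, v, h: float):
    return model.cdf(u, v, h)


def spatial_mixture_hfunc(model: SpatialMixtureCopula, u, v, h: float):
    return model.hfunc(u, v, h)


def spatial_mixture_hinv(model: SpatialMixtureCopula, t, v, h: float):
    return model.hinv(t, v, h)


@dataclass
class FitConfig:
    """Configuration for the full modelling pipeline.

    ``cutoff=None`` selects the cut-off automatically from the correlogram
    plateau rule; the faithful way to reproduce a published analysis is to
    supply the cut-off directly. ``student_t`` is a valid candidate family
    but not a default: its degrees of freedom are profiled over a grid,
    which multiplies fit cost.
    """

    cutoff: float | None = None
    n_bins: int = 10
    marginal_families: tuple[str, ...] = MARGINAL_FAMILIES
    copula_families: tuple[str, ...] = ("gaussian", "clayton", "frank", "gumbel", "joe")
    weights: tuple[float, ...] | None = None  # None -> equal 1/m
    pseudo_obs: str = "parametric"  # or "rank"
    epsilon_tau: float = 0.05  # plateau threshold for auto cutoff
    selection_criterion: str = "loglik"  # or "aic" (penalises student_t)


def _pseudo_observations(dataset: SpatialDataset, marginals, how: str) -> np.ndarray:
    if how == "rank":
        from scipy.stats import rankdata

        return rankdata(dataset.values, axis=0) / (dataset.n + 1.0)
    u = np.empty_like(dataset.values)
    for l, marg in enumerate(marginals):
        u[:, l] = marginal_transform(marg, dataset.values[:, l], "cdf")
    return u


def fit_spatial_mixture(dataset: SpatialDataset, config: FitConfig | None = None) -> SpatialMixtureCopula:
    """Run the full modelling pipeline on a dataset.

    Fits marginals per variable, builds pseudo-observations, bins the
    location pairs up to the cut-off, fits one copula per variable per bin
    by ML family selection, mixes them per bin with the configured weights,
    and assembles the distance-dependent convex combination. With a single
    variable this degenerates to the univariate spatial pair-copula model.
    """
    config = config or FitConfig()
    m = dataset.m
    if config.weights is None:
        weights = np.full(m, 1.0 / m)
    else:
        weights = np.asarray(config.weights, dtype=float)
        if weights.size != m:
            raise SupportError("one mixture weight per variable required")

    marginals = [select_marginal(dataset.values[:, l], config.marginal_families) for l in range(m)]
    for l, marg in enumerate(marginals):
        log.info("marginal %s: %s %s loglik %.2f", dataset.names[l], marg.family,
                 marg.params, marg.loglik)
    u = _pseudo_observations(dataset, marginals, config.pseudo_obs)

    pairs = pairwise_distances(dataset.coords)
    if config.cutoff is None:
        hmax = float(pairs.h.max())
        probe = bin_pairs(pairs, hmax * (1.0 + 1e-9), max(config.n_bins, 10))
        corr = empirical_correlogram(SpatialDataset(dataset.coords, dataset.values,
                                                    list(dataset.names),
                                                    allow_duplicate_locations=True), probe)
        cutoff = select_cutoff(corr, config.epsilon_tau)
        log.info("auto-selected cutoff %.1f m", cutoff)
    else:
        cutoff = float(config.cutoff)
    binning = bin_pairs(pairs, cutoff, config.n_bins)

    bin_mixtures: list[MixtureCopula] = []
    for k, mem in enumerate(binning.members):
        comps: list[CopulaModel] = []
        for l in range(m):
            if len(mem) < 10:
                log.warning("bin %d has %d pairs for %s: using independence",
                            k + 1, len(mem), dataset.names[l])
                comps.append(CopulaModel("independence"))
                continue
            try:
                fit = select_copula(u[mem.i, l], u[mem.j, l], config.copula_families,
                                    criterion=config.selection_criterion)
            except FitError as exc:
                raise FitError(f"bin {k + 1}, variable {dataset.names[l]}: {exc}") from exc
            log.info("bin %d %s: %s theta=%s rot=%d loglik=%.2f (%d pairs)",
                     k + 1, dataset.names[l], fit.family, fit.theta, fit.rotation,
                     fit.loglik, len(mem))
            comps.append(fit)
        bin_mixtures.append(build_bin_mixture(comps, weights))

    return SpatialMixtureCopula(
        binning=binning,
        bin_mixtures=bin_mixtures,
        lambdas=lambda_weights(binning),
        marginals=marginals,
        weights=weights,
        names=list(dataset.names),
    )


def with_weights(model: SpatialMixtureCopula, weights) -> SpatialMixtureCopula:
    """Rebuild the model with new mixture weights, reusing all fitted
    per-bin copulas (weights do not enter the per-variable fits)."""
    weights = np.asarray(weights, dtype=float)
    mixtures = [build_bin_mixture(mix.components, weights) for mix in model.bin_mixtures]
    return SpatialMixtureCopula(model.binning, mixtures, model.lambdas,
                                model.marginals, weights, list(model.names))


def univariate_submodel(model: SpatialMixtureCopula, variable: int) -> SpatialMixtureCopula:
    """The m=1 pair-copula baseline for one variable: the same binning and
    marginals, but each bin keeps only that variable's fitted copula."""
    mixtures = [build_bin_mixture([mix.components[variable]], [1.0])
                for mix in model.bin_mixtures]
    return SpatialMixtureCopula(model.binning, mixtures, model.lambdas,
                                model.marginals, np.array([1.0]), list(model.names))


def optimize_weights(dataset: SpatialDataset, model: SpatialMixtureCopula,
                     grid, target: int = 0) -> float:
    """Grid search over the first variable's mixture weight ``w_1``
    (bivariate case), minimising faithful-mode RMSE of the target variable
    at the sampled locations. Returns the best ``w_1``. The default
    pipeline keeps equal weights; this search is opt-in."""
    from .prediction import PredictionConfig, predict_variable
    from .validation import error_metrics

    if model.m != 2:
        raise SupportError("weight optimisation is implemented for m = 2")
    grid = [float(w) for w in grid]
    if any(not 0.0 < w < 1.0 for w in grid):
        raise SupportError("grid weights must lie strictly inside (0, 1)")
    best_w, best_rmse = None, np.inf
    cfg = PredictionConfig(target=target, mode="faithful")
    for w1 in grid:
        cand = with_weights(model, (w1, 1.0 - w1))
        res = predict_variable(cand, dataset, cfg)
        rmse = error_metrics(dataset.values[:, target], res.predicted).rmse
        log.info("weight w1=%.3f -> RMSE %.5f", w1, rmse)
        if rmse < best_rmse:
            best_w, best_rmse = w1, rmse
    return best_w
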