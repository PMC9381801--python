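"""Cross-validation metrics: MAE, RMSE, MAPE and bivariate KDE MSE.

The model is validated by predicting each variable from the other at the
sampled locations and comparing against the observed values. MAPE is
reported on the ratio scale (0.5 means 50%). Reproduction of the joint
(bivariate) relationship is scored by the mean squared difference between
Gaussian-kernel density estimates of the actual and predicted point
clouds on a shared grid; its absolute value depends on the grid and
bandwidth conventions, so it is comparable only across methods evaluated
with the same settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dataset import SpatialDataset
from .errors import SupportError
from .mixture import FitConfig, SpatialMixtureCopula, fit_spatial_mixture, univariate_submodel
from .prediction import PredictionConfig, predict_variable

__all__ = ["ErrorMetrics", "ValidationReport", "error_metrics", "kde_mse", "cross_validate"]

log = logging.getLogger(__name__)


class ErrorMetrics(NamedTuple):
    mae: float
    rmse: float
    mape: float


def error_metrics(actual, predicted) -> ErrorMetrics:
    """MAE, RMSE and MAPE (ratio scale) of predictions against actuals.

    Elements with a zero actual are excluded from MAPE only, with the
    exclusion count logged.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size or actual.size < 1:
        raise SupportError("need equal-length non-empty vectors")
    err = actual - predicted
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    nonzero = actual != 0.0
    if not np.all(nonzero):
        log.warning("MAPE excludes %d zero actuals", int((~nonzero).sum()))
    if not np.any(nonzero):
        raise SupportError("MAPE undefined: all actuals are zero")
    mape = float((np.abs(err[nonzero]) / np.abs(actual[nonzero])).mean())
    return ErrorMetrics(mae=mae, rmse=rmse, mape=mape)


def _silverman_bandwidths(cloud: np.ndarray) -> np.ndarray:
    # per-axis Silverman rule for a bivariate Gaussian product kernel
    n, d = cloud.shape
    sd = cloud.std(axis=0, ddof=1)
    if np.any(sd <= 0.0):
        raise SupportError("degenerate (zero-variance) cloud")
    return sd * (n * (d + 2.0) / 4.0) ** (-1.0 / (d + 4.0))


def _kde_on_grid(cloud: np.ndarray, gx: np.ndarray, gy: np.ndarray,
                 bw: np.ndarray) -> np.ndarray:
    dx = (gx[:, None, None] - cloud[None, None, :, 0]) / bw[0]
    dy = (gy[None, :, None] - cloud[None, None, :, 1]) / bw[1]
    kern = np.exp(-0.5 * (dx ** 2 + dy ** 2))
    norm = 2.0 * np.pi * bw[0] * bw[1] * cloud.shape[0]
    return kern.sum(axis=2) / norm


def kde_mse(actual_pairs, predicted_pairs, grid: int = 50,
            bandwidth="silverman", padding: float = 0.1) -> float:
    """Mean squared difference of the two clouds' bivariate KDEs.

    Both densities use a Gaussian product kernel with per-cloud, per-axis
    Silverman bandwidths (or explicit ``(bx, by)``), evaluated on a shared
    ``grid x grid`` lattice spanning the union range of the clouds padded
    by ``padding`` on each side.
    """
    a = np.asarray(actual_pairs, dtype=float)
    p = np.asarray(predicted_pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or p.ndim != 2 or p.shape[1] != 2:
        raise SupportError("point clouds must have shape (n, 2)")
    if a.shape[0] < 5 or p.shape[0] < 5:
        raise SupportError("need at least 5 pairs per cloud")
    lo = np.minimum(a.min(axis=0), p.min(axis=0))
    hi = np.maximum(a.max(axis=0), p.max(axis=0))
    span = hi - lo
    lo, hi = lo - padding * span, hi + padding * span
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    if bandwidth == "silverman":
        bw_a, bw_p = _silverman_bandwidths(a), _silverman_bandwidths(p)
    else:
        bw_a = bw_p = np.asarray(bandwidth, dtype=float)
        if np.any(bw_a <= 0):
            raise SupportError("bandwidths must be positive")
    da = _kde_on_grid(a, gx, gy, bw_a)
    dp = _kde_on_grid(p, gx, gy, bw_p)
    return float(((da - dp) ** 2).mean())


@dataclass
class ValidationReport:
    """Table-style cross-validation summary for one method."""

    method: str
    n: int
    metrics: dict[str, ErrorMetrics]  # per variable name
    kde_mse: float

    def to_dict(self) -> dict:
        out = {"method": self.method, "n": self.n, "kde_mse": self.kde_mse}
        for name, m in self.metrics.items():
            out[name] = {"mae": m.mae, "rmse": m.rmse, "mape": m.mape}
        return out


def cross_validate(dataset: SpatialDataset, fit_config: FitConfig | None = None,
                   prediction_config: PredictionConfig | None = None,
                   model: SpatialMixtureCopula | None = None,
                   baseline: bool = False) -> ValidationReport:
    """Predict each variable given the other at all sampled locations and
    score the result.

    The model is fitted on the full dataset and evaluated at the sampled
    locations (faithful mode by default). With ``baseline=True`` each
    variable is predicted with its own m=1 pair-copula submodel (same
    binning, same per-bin fits, no cross-variable mixing) — the univariate
    comparison scenario.
    """
    if dataset.m != 2:
        raise SupportError("cross-validation is bivariate (m = 2)")
    if model is None:
        model = fit_spatial_mixture(dataset, fit_config)
    base_pc = prediction_config or PredictionConfig(mode="faithful")

    preds = {}
    metrics = {}
    for tgt in (0, 1):
        use = model if not baseline else univariate_submodel(model, tgt)
        pc = PredictionConfig(target=tgt, mode=base_pc.mode,
                              h_policy=base_pc.h_policy, h_value=base_pc.h_value)
        res = predict_variable(use, dataset, pc)
        preds[tgt] = res.predicted
        metrics[dataset.names[tgt]] = error_metrics(dataset.values[:, tgt], res.predicted)

    joint = kde_mse(dataset.values, np.column_stack([preds[0], preds[1]]))
    return ValidationReport(
        method="univariate" if baseline else "mixture",
        n=dataset.n, metrics=metrics, kde_mse=joint,
    )
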