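"""Pairwise distances, spatial binning and Kendall-tau correlograms.

Spatial dependence is summarised over distance classes ("bins"): all
location pairs whose separation falls in the half-open interval
``[h_{k-1}, h_k)`` share one fitted copula. The correlogram — Kendall's
tau per bin against the bin's mean pair distance — shows how dependence
decays with distance and drives the choice of the cut-off distance beyond
which pairs are treated as independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.spatial.distance import pdist

from .dataset import SpatialDataset
from .errors import SupportError

__all__ = [
    "Pairs",
    "BinningScheme",
    "Correlogram",
    "pairwise_distances",
    "bin_pairs",
    "kendall_tau",
    "empirical_correlogram",
    "select_cutoff",
    "smooth_correlogram",
]

log = logging.getLogger(__name__)


class Pairs(NamedTuple):
    """Unordered distinct location pairs ``i < j`` with Euclidean distance."""

    i: np.ndarray
    j: np.ndarray
    h: np.ndarray

    def __len__(self) -> int:
        return self.h.size


def pairwise_distances(coords) -> Pairs:
    """All n(n-1)/2 distinct unordered pairs with Euclidean distances.

    Self-pairs are excluded: a location paired with itself is comonotone by
    construction and contributes nothing to copula estimation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise SupportError("coords must have shape (n, 2)")
    if not np.all(np.isfinite(coords)):
        raise SupportError("non-finite coordinates")
    n = coords.shape[0]
    if n < 2:
        empty = np.empty(0)
        return Pairs(empty.astype(int), empty.astype(int), empty)
    i, j = np.triu_indices(n, k=1)
    return Pairs(i, j, pdist(coords))


@dataclass
class BinningScheme:
    """Equal-width distance classes up to a cut-off.

    ``edges`` are ``h_0 = 0 < h_1 < ... < h_K = cutoff``; bin ``k`` (1-based)
    covers ``[h_{k-1}, h_k)``. Pairs at or beyond the cut-off are excluded
    (independence region). ``mean_distances[k-1]`` is NaN for an empty bin.
    """

    cutoff: float
    n_bins: int
    edges: np.ndarray
    members: list[Pairs]
    mean_distances: np.ndarray
    counts: np.ndarray
    n_excluded: int = 0

    def width(self) -> float:
        return self.cutoff / self.n_bins

    def bin_of(self, h: float) -> int | None:
        """1-based bin index of a distance, or None beyond the cut-off."""
        if h >= self.cutoff:
            return None
        return min(int(h // self.width()) + 1, self.n_bins)


def bin_pairs(pairs: Pairs, cutoff: float, n_bins: int) -> BinningScheme:
    """Partition pairs into ``n_bins`` equally spaced bins on [0, cutoff)."""
    if cutoff <= 0:
        raise SupportError("cutoff must be positive")
    if n_bins < 1:
        raise SupportError("need at least one bin")
    edges = np.linspace(0.0, cutoff, n_bins + 1)
    h = np.asarray(pairs.h, dtype=float)
    inside = h < cutoff
    idx = np.minimum((h[inside] / (cutoff / n_bins)).astype(int), n_bins - 1)
    members: list[Pairs] = []
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    i_in, j_in, h_in = pairs.i[inside], pairs.j[inside], h[inside]
    for k in range(n_bins):
        sel = idx == k
        members.append(Pairs(i_in[sel], j_in[sel], h_in[sel]))
        counts[k] = int(sel.sum())
        if counts[k]:
            means[k] = h_in[sel].mean()
        else:
            log.warning("spatial bin %d [%g, %g) is empty", k + 1, edges[k], edges[k + 1])
    return BinningScheme(
        cutoff=float(cutoff),
        n_bins=n_bins,
        edges=edges,
        members=members,
        mean_distances=means,
        counts=counts,
        n_excluded=int((~inside).sum()),
    )


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise SupportError("need two equal-length samples of size >= 2")
    tau = stats.kendalltau(x, y).statistic
    if not np.isfinite(tau):
        raise SupportError("Kendall tau undefined (all values tied in one sample)")
    return float(tau)


@dataclass
class Correlogram:
    """Per-bin Kendall tau for each variable against mean pair distance."""

    mean_distances: np.ndarray
    taus: np.ndarray  # (n_bins, m); NaN where the bin is empty
    counts: np.ndarray
    edges: np.ndarray
    names: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.taus.shape[0]


def empirical_correlogram(dataset: SpatialDataset, binning: BinningScheme) -> Correlogram:
    """Kendall tau of ``(Z_l(x_i), Z_l(x_j))`` over each bin's pairs, per
    variable. Empty bins get NaN and a logged warning."""
    taus = np.full((binning.n_bins, dataset.m), np.nan)
    for k, mem in enumerate(binning.members):
        if len(mem) < 2:
            log.warning("bin %d has %d pairs; tau not computed", k + 1, len(mem))
            continue
        for l in range(dataset.m):
            z = dataset.values[:, l]
            try:
                taus[k, l] = kendall_tau(z[mem.i], z[mem.j])
            except SupportError:
                log.warning("tau undefined in bin %d for %s", k + 1, dataset.names[l])
    return Correlogram(
        mean_distances=binning.mean_distances.copy(),
        taus=taus,
        counts=binning.counts.copy(),
        edges=binning.edges.copy(),
        names=list(dataset.names),
    )


def smooth_correlogram(correlogram: Correlogram, variable: int = 0, lam: float | None = None):
    """Cubic smoothing spline through one variable's (mean distance, tau)
    points — the smooth curve drawn over a correlogram plot. Returns a
    callable spline."""
    ok = np.isfinite(correlogram.taus[:, variable]) & np.isfinite(correlogram.mean_distances)
    if ok.sum() < 4:
        raise SupportError("need at least 4 non-empty bins to smooth")
    return make_smoothing_spline(
        correlogram.mean_distances[ok], correlogram.taus[ok, variable], lam=lam
    )


def select_cutoff(correlogram: Correlogram, epsilon: float = 0.05) -> float:
    """Automated surrogate for the visual plateau rule.

    Returns the smallest bin upper edge beyond which the per-bin tau
    (maximum across variables; cubic interpolation of the correlogram
    coincides with these values at the bin means) stays below ``epsilon``
    for all remaining bins. Falls back to the largest edge, with a warning,
    if dependence never drops below the threshold.
    """
    taus = correlogram.taus
    stat = np.nanmax(np.abs(taus), axis=1)
    nonempty = np.isfinite(stat)
    if nonempty.sum() < 2:
        raise SupportError("need at least 2 non-empty bins to select a cutoff")
    above = np.where(nonempty & (stat >= epsilon))[0]
    if above.size == 0:
        return float(correlogram.edges[1])
    last = int(above[-1])
    if last == correlogram.n_bins - 1:
        log.warning(
            "tau never plateaus below %.3g within the binned range; "
            "falling back to the largest edge", epsilon,
        )
    return float(correlogram.edges[last + 1])
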