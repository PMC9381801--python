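"""Container for point-sampled multivariate spatial data.

A :class:`SpatialDataset` holds ``n`` planar locations (metric coordinates)
together with ``m`` co-located variable columns — the basic input to the
spatial mixture copula pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatialDataset"]


@dataclass
class SpatialDataset:
    """Point samples of ``m`` variables observed at ``n`` 2-D locations.

    Parameters
    ----------
    coords
        Array of shape ``(n, 2)``; planar coordinates in metres.
    values
        Array of shape ``(n, m)``; one column per variable.
    names
        ``m`` variable labels.
    allow_duplicate_locations
        Duplicated location rows produce zero-distance pairs, which are
        comonotone by construction and carry no copula information; they
        are rejected unless explicitly allowed.
    """

    coords: np.ndarray
    values: np.ndarray
    names: list[str] = field(default_factory=list)
    allow_duplicate_locations: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if self.values.shape[0] != self.coords.shape[0]:
            raise ValueError("coords and values must have the same number of rows")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")
        if not self.names:
            self.names = [f"z{l + 1}" for l in range(self.values.shape[1])]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per variable column required")
        if not self.allow_duplicate_locations:
            uniq = np.unique(self.coords, axis=0)
            if uniq.shape[0] != self.coords.shape[0]:
                raise ValueError(
                    "duplicated location rows (pass allow_duplicate_locations=True "
                    "to keep them; they create zero-distance pairs)"
                )

    @property
    def n(self) -> int:
        """Number of sampled locations."""
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        """Number of co-located variables."""
        return self.values.shape[1]

    def variable(self, which: int | str) -> np.ndarray:
        """Return one variable column, by index or by name."""
        if isinstance(which, str):
            which = self.names.index(which)
        return self.values[:, which]
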