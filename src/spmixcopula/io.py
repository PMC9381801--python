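"""CSV input, model serialization, and configuration loading.

A fitted :class:`~spmixcopula.mixture.SpatialMixtureCopula` serialises to
a versioned JSON document that round-trips losslessly: floats are written
at full precision (JSON ``repr`` round-trip), lambdas additionally as
exact numerator/denominator pairs, so a re-read model evaluates
bit-identically. Display values (2-decimal lambdas) are included for
human readers but never read back.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpatialDataset
from .errors import SupportError
from .families import CopulaModel
from .geometry import BinningScheme, Pairs
from .marginals import MarginalModel
from .mixture import MixtureCopula, SpatialMixtureCopula, format_lambda

__all__ = ["read_points_csv", "write_model", "read_model", "model_to_dict",
           "model_from_dict", "SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def read_points_csv(path, x_col: str = "x", y_col: str = "y",
                    value_cols=None, drop_zeros: bool = False) -> SpatialDataset:
    """Read a point-sample table into a :class:`SpatialDataset`.

    Rows with missing values in the used columns are dropped (count
    logged). ``drop_zeros=True`` additionally drops rows where any value
    column is zero — the convention of keeping only non-zero measurements.
    """
    df = pd.read_csv(path)
    if value_cols is None:
        value_cols = [c for c in df.columns if c not in (x_col, y_col)]
    missing = [c for c in [x_col, y_col, *value_cols] if c not in df.columns]
    if missing:
        raise SupportError(f"missing columns in {path}: {missing}")
    used = df[[x_col, y_col, *value_cols]].apply(pd.to_numeric, errors="coerce")
    ok = used.notna().all(axis=1)
    if (~ok).any():
        log.warning("dropped %d rows with missing/non-numeric cells", int((~ok).sum()))
    used = used[ok]
    if drop_zeros:
        nz = (used[value_cols] != 0.0).all(axis=1)
        if (~nz).any():
            log.info("dropped %d rows with zero values", int((~nz).sum()))
        used = used[nz]
    return SpatialDataset(
        coords=used[[x_col, y_col]].to_numpy(float),
        values=used[value_cols].to_numpy(float),
        names=list(value_cols),
        allow_duplicate_locations=True,
    )


def _copula_doc(c: CopulaModel) -> dict:
    return {"family": c.family, "theta": list(c.theta), "rotation": c.rotation,
            "loglik": c.loglik}


def _copula_from_doc(d: dict) -> CopulaModel:
    return CopulaModel(family=d["family"], theta=tuple(d["theta"]),
                       rotation=int(d["rotation"]), loglik=d.get("loglik"))


def model_to_dict(model: SpatialMixtureCopula, provenance: dict | None = None) -> dict:
    b = model.binning
    return {
        "schema_version": SCHEMA_VERSION,
        "names": list(model.names),
        "marginals": [
            {"family": m.family, "params": m.params, "loglik": m.loglik, "n": m.n,
             "candidate_logliks": m.candidate_logliks}
            for m in model.marginals
        ],
        "binning": {
            "cutoff": b.cutoff,
            "n_bins": b.n_bins,
            "edges": b.edges.tolist(),
            "mean_distances": [None if not np.isfinite(x) else float(x)
                               for x in b.mean_distances],
            "counts": b.counts.tolist(),
            "n_excluded": b.n_excluded,
        },
        "weights": model.weights.tolist(),
        "copulas": [[_copula_doc(c) for c in mix.components] for mix in model.bin_mixtures],
        "lambdas": [{"num": lam.numerator, "den": lam.denominator,
                     "display": format_lambda(lam)} for lam in model.lambdas],
        "provenance": {
            "created": datetime.now(timezone.utc).isoformat(),
            **(provenance or {}),
        },
    }


def model_from_dict(doc: dict) -> SpatialMixtureCopula:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SupportError(f"unsupported model schema version {version!r} "
                           f"(expected {SCHEMA_VERSION})")
    b = doc["binning"]
    empty = Pairs(np.empty(0, int), np.empty(0, int), np.empty(0))
    binning = BinningScheme(
        cutoff=float(b["cutoff"]),
        n_bins=int(b["n_bins"]),
        edges=np.asarray(b["edges"], dtype=float),
        members=[empty] * int(b["n_bins"]),  # pair membership is not persisted
        mean_distances=np.asarray([np.nan if x is None else x
                                   for x in b["mean_distances"]], dtype=float),
        counts=np.asarray(b["counts"], dtype=int),
        n_excluded=int(b.get("n_excluded", 0)),
    )
    weights = np.asarray(doc["weights"], dtype=float)
    marginals = [
        MarginalModel(family=m["family"], params=dict(m["params"]),
                      loglik=float(m["loglik"]), n=int(m["n"]),
                      candidate_logliks=dict(m.get("candidate_logliks") or {}))
        for m in doc["marginals"]
    ]
    mixtures = [MixtureCopula([_copula_from_doc(c) for c in comps], weights)
                for comps in doc["copulas"]]
    lambdas = [Fraction(d["num"], d["den"]) for d in doc["lambdas"]]
    return SpatialMixtureCopula(binning=binning, bin_mixtures=mixtures,
                                lambdas=lambdas, marginals=marginals,
                                weights=weights, names=list(doc["names"]))


def write_model(model: SpatialMixtureCopula, path, provenance: dict | None = None) -> None:
    doc = model_to_dict(model, provenance)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model(path) -> SpatialMixtureCopula:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SupportError(f"cannot parse model document {path}: {exc}") from exc
    return model_from_dict(doc)
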