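"""Point-referenced forest-inventory datasets: I/O, standardization, splits, distances.

Each spatial unit is one inventory record located at projected planar
coordinates ``(u, v)`` in meters, carrying five stand/terrain covariates
(NLT: living-tree density in stems/ha; canopy: canopy closure as a
fraction; H: mean stand height in m; slope: degrees; DBH: mean diameter
at breast height in cm) and two responses: a binary down-wood occurrence
indicator ``odw`` and a non-negative down-wood count ``ndw`` (stems/ha).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

#: canonical covariate order used throughout the package
COVARIATES = ["NLT", "canopy", "H", "slope", "DBH"]

#: canonical CSV column order
CSV_COLUMNS = ["id", "u", "v", *COVARIATES, "ODW", "NDW"]


class SchemaError(ValueError):
    """A required column is missing or a column cannot be parsed."""


class ValidationError(ValueError):
    """A dataset invariant is violated."""


@dataclass(frozen=True)
class SpatialDataset:
    """Immutable container for ``n`` point-referenced spatial units.

    Attributes
    ----------
    unit_id : ndarray of shape (n,)
        Unique unit identifiers.
    coords : ndarray of shape (n, 2)
        Projected planar coordinates ``(u, v)`` in meters.
    X : pandas.DataFrame of shape (n, k)
        Covariate matrix with named columns (default :data:`COVARIATES`).
    odw : ndarray of shape (n,)
        Binary occurrence response in {0, 1}.
    ndw : ndarray of shape (n,)
        Non-negative integer count response.
    """

    unit_id: np.ndarray
    coords: np.ndarray
    X: pd.DataFrame
    odw: np.ndarray
    ndw: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.unit_id)
        if self.coords.shape != (n, 2):
            raise ValidationError(f"coords must have shape ({n}, 2), got {self.coords.shape}")
        if len(self.X) != n or len(self.odw) != n or len(self.ndw) != n:
            raise ValidationError("all fields must have one row per unit")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("all coordinates must be finite")
        if len(np.unique(self.unit_id)) != n:
            raise ValidationError("duplicated unit_id values")
        if self.X.isna().any().any():
            raise ValidationError("covariate columns must have zero missing values")
        if not np.all(np.isin(self.odw, (0, 1))):
            raise ValidationError("invariant violated: odw must lie in {0, 1}")
        ndw = np.asarray(self.ndw, dtype=float)
        if np.any(ndw < 0) or np.any(ndw != np.round(ndw)):
            raise ValidationError("invariant violated: ndw must be non-negative and integer-valued")

    @property
    def n(self) -> int:
        return len(self.unit_id)

    def response(self, name: str) -> np.ndarray:
        if name == "odw":
            return np.asarray(self.odw, dtype=float)
        if name == "ndw":
            return np.asarray(self.ndw, dtype=float)
        raise KeyError(f"unknown response {name!r}; expected 'odw' or 'ndw'")

    def subset(self, index: np.ndarray) -> "SpatialDataset":
        return SpatialDataset(
            unit_id=self.unit_id[index],
            coords=self.coords[index],
            X=self.X.iloc[index].reset_index(drop=True),
            odw=self.odw[index],
            ndw=self.ndw[index],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.unit_id, "u": self.coords[:, 0], "v": self.coords[:, 1]})
        for c in self.X.columns:
            df[c] = self.X[c].to_numpy()
        df["ODW"] = self.odw
        df["NDW"] = self.ndw
        return df


@dataclass(frozen=True)
class StandardizationParams:
    """Per-column centers and scales used for z-scoring covariates."""

    center: pd.Series
    scale: pd.Series

    def __post_init__(self) -> None:
        bad = self.scale.index[~(self.scale > 0)]
        if len(bad):
            raise ValidationError(f"zero-variance column(s): {list(bad)}")

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.center.index] - self.center) / self.scale

    def invert(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.center.index] * self.scale + self.center


DEFAULT_SCHEMA = {
    "id": "id",
    "u": "u",
    "v": "v",
    "ODW": "ODW",
    "NDW": "NDW",
    **{c: c for c in COVARIATES},
}


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows with missing values; return (clean frame, n rejected)."""
    keep = df.notna().all(axis=1)
    return df[keep].reset_index(drop=True), int((~keep).sum())


def from_frame(df: pd.DataFrame, schema: dict[str, str] | None = None) -> SpatialDataset:
    """Build a validated :class:`SpatialDataset` from a dataframe.

    ``schema`` maps canonical names (``id``, ``u``, ``v``, covariates,
    ``ODW``, ``NDW``) to the columns actually present; ``id`` is optional
    and auto-generated as the 0-based row index when absent.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    required = [k for k in schema if k != "id"]
    missing = [schema[k] for k in required if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    numeric_cols = ["u", "v", *COVARIATES, "ODW", "NDW"]
    parsed = {}
    for key in numeric_cols:
        col = pd.to_numeric(df[schema[key]], errors="coerce")
        bad = col.isna() & df[schema[key]].notna()
        if bad.any():
            raise SchemaError(
                f"non-numeric values in column {schema[key]!r} at rows {list(df.index[bad])}"
            )
        parsed[key] = col

    work = pd.DataFrame(parsed)
    if schema["id"] in df.columns:
        work.insert(0, "_id", df[schema["id"]].to_numpy())
    work, n_rejected = _validate_rows(work)
    if n_rejected:
        import logging

        logging.getLogger(__name__).warning("rejected %d row(s) with missing values", n_rejected)
    ids = work["_id"].to_numpy() if "_id" in work.columns else np.arange(len(work))

    return SpatialDataset(
        unit_id=np.asarray(ids),
        coords=work[["u", "v"]].to_numpy(dtype=float),
        X=work[COVARIATES],
        odw=work["ODW"].to_numpy(dtype=int),
        ndw=work["NDW"].to_numpy(dtype=int),
    )


def load_dataset(path: str | Path, schema: dict[str, str] | None = None) -> SpatialDataset:
    """Load a dataset from CSV or GeoJSON (Point features)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        gj = json.loads(path.read_text())
        rows = []
        for feat in gj["features"]:
            geom = feat["geometry"]
            if geom["type"] != "Point":
                raise SchemaError("only Point features are supported")
            rows.append({"u": geom["coordinates"][0], "v": geom["coordinates"][1],
                         **feat.get("properties", {})})
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return from_frame(df, schema)


def write_dataset(ds: SpatialDataset, path: str | Path) -> None:
    """Write a dataset as CSV in the canonical column order."""
    ds.to_frame().to_csv(path, index=False)


def standardize(
    ds: SpatialDataset, params: StandardizationParams | None = None
) -> tuple[SpatialDataset, StandardizationParams]:
    """Z-score the covariate columns.

    When ``params`` is None the centers/scales are computed from ``ds``
    (sample sd, ddof=1) so the returned columns have mean 0 and unit sd;
    otherwise the given params are applied unchanged — a validation set
    is standardized with the training set's params.
    """
    if params is None:
        center = ds.X.mean()
        scale = ds.X.std(ddof=1)
        zero = scale.index[~(scale > 0)]
        if len(zero):
            raise ValidationError(f"zero-variance column(s): {list(zero)}")
        params = StandardizationParams(center=center, scale=scale)
    out = SpatialDataset(
        unit_id=ds.unit_id, coords=ds.coords, X=params.apply(ds.X), odw=ds.odw, ndw=ds.ndw
    )
    return out, params


def split_train_validation(
    ds: SpatialDataset, n_train: int, seed: int
) -> tuple[SpatialDataset, SpatialDataset]:
    """Uniform random split without replacement, reproducible from ``seed``."""
    if not 0 < n_train < ds.n:
        raise ValueError(f"n_train must be in (0, {ds.n}), got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    return ds.subset(np.sort(perm[:n_train])), ds.subset(np.sort(perm[n_train:]))


def distance_matrix(ds_or_coords: SpatialDataset | np.ndarray) -> np.ndarray:
    """Square symmetric matrix of Euclidean distances (meters)."""
    coords = ds_or_coords.coords if isinstance(ds_or_coords, SpatialDataset) else np.asarray(ds_or_coords)
    D = cdist(coords, coords)
    np.fill_diagonal(D, 0.0)
    return D


def cross_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from each row of ``a`` to each row of ``b`` (meters)."""
    return cdist(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
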