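"""Cluster-covariate assembly: extraction, collinearity screen, scaling.

The design matrix is built by nearest-cell lookup of each covariate
raster at the cluster coordinates, screened for near-duplicate covariate
pairs with a Pearson-correlation cutoff, and standardized column-wise
(the standardization record is kept for prediction-time reuse and
back-transformation of coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import CovariateStack, GridGeometry

__all__ = [
    "DesignMatrix",
    "ScreenResult",
    "read_clusters",
    "extract_covariates",
    "correlation_screen",
    "standardize",
    "standardize_cells",
    "clusters_to_data",
]

CLUSTER_COLUMNS = ["survey_year", "cluster_id", "lon", "lat", "births", "deaths"]


def read_clusters(path: str | Path) -> pd.DataFrame:
    """Read the cluster observation CSV and validate its invariants."""
    df = pd.read_csv(path)
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cluster table missing columns: {missing}")
    if (df["deaths"] > df["births"]).any() or (df["deaths"] < 0).any():
        bad = df.loc[(df["deaths"] > df["births"]) | (df["deaths"] < 0),
                     "cluster_id"].tolist()
        raise ValueError(f"clusters with deaths outside [0, births]: {bad}")
    if (df["births"] < 1).any():
        bad = df.loc[df["births"] < 1, "cluster_id"].tolist()
        raise ValueError(f"clusters with no live births cannot be modelled: {bad}")
    return df


@dataclass
class DesignMatrix:
    """Per-cluster covariate values plus the standardization record."""

    X: np.ndarray                 # (n_clusters, n_covariates)
    names: list[str]
    cluster_ids: np.ndarray
    means: np.ndarray | None = None   # set once standardized
    sds: np.ndarray | None = None

    @property
    def standardized(self) -> bool:
        return self.means is not None

    def subset(self, names: list[str]) -> "DesignMatrix":
        idx = [self.names.index(n) for n in names]
        return DesignMatrix(
            X=self.X[:, idx],
            names=list(names),
            cluster_ids=self.cluster_ids,
            means=None if self.means is None else self.means[idx],
            sds=None if self.sds is None else self.sds[idx],
        )

    def back_transform(self) -> np.ndarray:
        """Undo standardization, returning the raw covariate values."""
        if not self.standardized:
            return self.X.copy()
        return self.X * self.sds + self.means


@dataclass
class ScreenResult:
    """Outcome of the pairwise-correlation collinearity screen."""

    retained: list[str]
    correlation: pd.DataFrame
    exclusions: list[dict]

    def report(self) -> str:
        lines = [f"retained ({len(self.retained)}): " + ", ".join(self.retained)]
        if not self.exclusions:
            lines.append("no covariates excluded")
        for e in self.exclusions:
            if e["reason"] == "zero variance":
                lines.append(f"excluded {e['excluded']}: zero variance")
            else:
                lines.append(
                    f"excluded {e['excluded']}: |r| = {abs(e['r']):.5f} with "
                    f"{e['kept']} (r = {e['r']:.5f})")
        return "\n".join(lines)


def extract_covariates(clusters: pd.DataFrame, rasters: CovariateStack,
                       names: list[str] | None = None) -> DesignMatrix:
    """Nearest-cell covariate values at each cluster location.

    Clusters falling outside the raster extent, or on NODATA cells, are
    reported by cluster_id in the raised error.
    """
    geom: GridGeometry = rasters.geometry
    names = list(names) if names is not None else rasters.names
    lon = clusters["lon"].to_numpy(dtype=float)
    lat = clusters["lat"].to_numpy(dtype=float)
    ids = clusters["cluster_id"].to_numpy()
    row, col = geom.cell_index(lon, lat)
    outside = (row < 0) | (col < 0)
    if outside.any():
        raise ValueError(
            f"clusters outside raster extent: {ids[outside].tolist()}")
    cols = []
    for name in names:
        rast = rasters[name]
        if not rast.mask.any():
            raise ValueError(f"covariate {name!r} is entirely NODATA")
        vals = rast.values[row, col]
        bad = ~rast.mask[row, col]
        if bad.any():
            raise ValueError(
                f"covariate {name!r} is NODATA at clusters: "
                f"{ids[bad].tolist()}")
        cols.append(vals)
    return DesignMatrix(X=np.column_stack(cols), names=names, cluster_ids=ids)


def correlation_screen(design: DesignMatrix, threshold: float = 0.8,
                       order: list[str] | None = None) -> ScreenResult:
    """Drop the later-ordered member of every |r| >= threshold pair.

    ``order`` is the declared covariate priority (defaults to the design's
    column order); for each offending pair the covariate appearing later
    is excluded.  Zero-variance columns are excluded with their own
    reason.  The screen is idempotent: re-screening the retained set
    excludes nothing.
    """
    order = list(order) if order is not None else list(design.names)
    unknown = [n for n in order if n not in design.names]
    if unknown:
        raise ValueError(f"screen order names not in design: {unknown}")
    ordered = [n for n in order if n in design.names] + \
        [n for n in design.names if n not in order]
    X = design.subset(ordered).X
    n, z = X.shape
    if z < 1:
        raise ValueError("need at least one covariate")

    sds = X.std(axis=0)
    exclusions: list[dict] = []
    active = []
    for j, name in enumerate(ordered):
        if sds[j] == 0:
            exclusions.append(
                {"excluded": name, "kept": None, "r": np.nan,
                 "reason": "zero variance"})
        else:
            active.append(j)

    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False) if z > 1 else np.ones((1, 1))
    corr_df = pd.DataFrame(corr, index=ordered, columns=ordered)

    retained_idx: list[int] = []
    for j in active:
        trigger = None
        for i in retained_idx:
            r = corr[i, j]
            if abs(r) >= threshold:
                trigger = (i, r)
                break
        if trigger is None:
            retained_idx.append(j)
        else:
            i, r = trigger
            exclusions.append(
                {"excluded": ordered[j], "kept": ordered[i], "r": float(r),
                 "reason": "correlation"})
    retained = [ordered[j] for j in retained_idx]
    return ScreenResult(retained=retained, correlation=corr_df,
                        exclusions=exclusions)


def standardize(design: DesignMatrix) -> DesignMatrix:
    """Center and scale each column by its own mean and SD."""
    if design.standardized:
        return design
    means = design.X.mean(axis=0)
    sds = design.X.std(axis=0)
    if np.any(sds == 0):
        bad = [n for n, s in zip(design.names, sds) if s == 0]
        raise ValueError(f"zero-SD covariates cannot be standardized: {bad}")
    return replace(design, X=(design.X - means) / sds, means=means, sds=sds)


def standardize_cells(stack: CovariateStack, design: DesignMatrix) -> np.ndarray:
    """Standardize the full raster stack with the training record.

    Returns a (ncells, n_covariates) matrix aligned with the design's
    retained covariates; NODATA cells come out as NaN.
    """
    if not design.standardized:
        raise ValueError("design must be standardized first")
    cols = []
    for k, name in enumerate(design.names):
        vals = stack[name].flat().astype(float)
        vals = np.where(stack[name].mask.ravel(), vals, np.nan)
        cols.append((vals - design.means[k]) / design.sds[k])
    return np.column_stack(cols)


def clusters_to_data(clusters: pd.DataFrame, geometry: GridGeometry):
    """Map the cluster table to model arrays (y, n, cell, survey index).

    Returns a :class:`geomort.model.ClusterData` plus the ordered list of
    survey years defining the survey index.
    """
    from .model import ClusterData

    years = sorted(clusters["survey_year"].unique())
    year_idx = {y: i for i, y in enumerate(years)}
    row, col = geometry.cell_index(
        clusters["lon"].to_numpy(float), clusters["lat"].to_numpy(float))
    if np.any(row < 0) or np.any(col < 0):
        bad = clusters["cluster_id"].to_numpy()[(row < 0) | (col < 0)]
        raise ValueError(f"clusters outside the model grid: {bad.tolist()}")
    data = ClusterData(
        y=clusters["deaths"].to_numpy(float),
        n=clusters["births"].to_numpy(float),
        cell=geometry.flat_index(row, col),
        survey=np.array([year_idx[y] for y in clusters["survey_year"]]),
    )
    return data, years
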