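"""Gridded raster containers and ESRI ASCII grid I/O.

Covariate surfaces and predicted mortality surfaces live on a single
regular lon/lat lattice.  Rows are stored north-to-south (row 0 is the
top of the grid), matching the ESRI ASCII ``.asc`` convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridGeometry",
    "Raster",
    "CovariateStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_regions",
    "write_regions",
]


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular grid in the ESRI ASCII convention.

    ``xllcorner``/``yllcorner`` are the coordinates of the *outer corner*
    of the lower-left cell; ``cellsize`` is the (square) cell edge length
    in the same units (degrees for lon/lat grids).
    """

    nrows: int
    ncols: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def ncells(self) -> int:
        return self.nrows * self.ncols

    @property
    def xurcorner(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def yurcorner(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Lon and lat of every cell center, each shaped (nrows, ncols)."""
        x = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        y = self.yurcorner - (np.arange(self.nrows) + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def cell_index(self, lon, lat):
        """Map coordinates to (row, col) of the containing cell.

        Points on an interior cell boundary are assigned by round-half-down
        on the fractional row/col index, i.e. the lower-indexed cell.
        Points outside the grid extent get index -1 (caller validates).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        u = (lon - self.xllcorner) / self.cellsize
        v = (self.yurcorner - lat) / self.cellsize
        col = np.ceil(u).astype(int) - 1
        row = np.ceil(v).astype(int) - 1
        # points exactly on the left/top outer edge are inside the grid
        col = np.where((u == 0.0), 0, col)
        row = np.where((v == 0.0), 0, row)
        inside = (u >= 0) & (u <= self.ncols) & (v >= 0) & (v <= self.nrows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def flat_index(self, row, col):
        return row * self.ncols + col


@dataclass
class Raster:
    """A single 2-D surface on a :class:`GridGeometry` lattice."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.geometry.nrows}, {self.geometry.ncols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~(np.isnan(self.values) | (self.values == self.geometry.nodata))

    def flat(self) -> np.ndarray:
        return self.values.ravel()


class CovariateStack:
    """An ordered set of co-registered covariate rasters (columns of X)."""

    def __init__(self, rasters: Mapping[str, Raster]):
        rasters = dict(rasters)
        if not rasters:
            raise ValueError("empty covariate stack")
        geoms = {r.geometry for r in rasters.values()}
        if len(geoms) != 1:
            raise ValueError("all rasters in a stack must share one grid")
        self._rasters = rasters

    @property
    def names(self) -> list[str]:
        return list(self._rasters)

    @property
    def geometry(self) -> GridGeometry:
        return next(iter(self._rasters.values())).geometry

    def __getitem__(self, name: str) -> Raster:
        return self._rasters[name]

    def __contains__(self, name: str) -> bool:
        return name in self._rasters

    def __len__(self) -> int:
        return len(self._rasters)

    def subset(self, names: Iterable[str]) -> "CovariateStack":
        return CovariateStack({n: self._rasters[n] for n in names})

    def as_matrix(self) -> np.ndarray:
        """Cells-by-covariates matrix, row-major over the grid."""
        return np.column_stack([self._rasters[n].flat() for n in self.names])

    def correlation_matrix(self) -> np.ndarray:
        return np.corrcoef(self.as_matrix(), rowvar=False)


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    g = raster.geometry
    path = Path(path)
    vals = np.where(raster.mask, raster.values, g.nodata)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.xllcorner!r}\n"
        f"yllcorner {g.yllcorner!r}\n"
        f"cellsize {g.cellsize!r}\n"
        f"NODATA_value {g.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (.asc) file."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field {req!r}")
    geom = GridGeometry(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
    values = np.where(values == geom.nodata, np.nan, values)
    return Raster(geom, values)


def write_regions(regions: list[tuple[str, BaseGeometry]], path: str | Path) -> Path:
    """Write named polygons as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"region_name": name},
            "geometry": geom.__geo_interface__,
        }
        for name, geom in regions
    ]
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def read_regions(path: str | Path) -> list[tuple[str, BaseGeometry]]:
    """Read a GeoJSON FeatureCollection of named region polygons."""
    with open(path) as fh:
        fc = json.load(fh)
    regions = []
    for feat in fc["features"]:
        name = feat.get("properties", {}).get("region_name", f"region_{len(regions)}")
        regions.append((name, shapely_shape(feat["geometry"])))
    return regions
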