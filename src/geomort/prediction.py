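"""Mortality surfaces, regional rate tables, trends and map export.

Rates follow the binomial-proportion convention: the under-five
mortality rate of a cell/region is 1000 times the posterior mean death
probability, so a cell with p = 0.121 reports 121 deaths per 1000 live
births.  Rounding to integers happens only when tables are written.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .model import ModelSpec
from .preprocessing import DesignMatrix, standardize_cells
from .rasters import CovariateStack, GridGeometry, Raster

__all__ = [
    "PredictedSurface",
    "predict_surface",
    "aggregate_regions",
    "trend_table",
    "render_maps",
]

STAGNATION_FRACTION = 0.05


@dataclass
class PredictedSurface:
    """Cell-wise posterior summaries of the mortality probability."""

    geometry: GridGeometry
    mean: np.ndarray      # (nrows, ncols), posterior mean of p
    lower: np.ndarray     # 2.5% quantile
    upper: np.ndarray     # 97.5% quantile
    survey_year: object = None

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.mean)

    @property
    def rate_per_1000(self) -> np.ndarray:
        return 1000.0 * self.mean


def predict_surface(samples, rasters: CovariateStack, spec: ModelSpec,
                    design: DesignMatrix, survey: int = 0,
                    survey_year=None) -> PredictedSurface:
    """Posterior mortality surface for one survey.

    Covariate cells are standardized with the training record before the
    linear predictor is formed; NODATA cells propagate to NaN summaries.
    """
    geom = rasters.geometry
    if geom != spec.geometry:
        raise ValueError("raster grid does not match the model grid")
    if list(design.names) != list(spec.covariates):
        raise ValueError("design covariates do not match the model spec")
    Xc = standardize_cells(rasters.subset(design.names), design) \
        if design.names else np.zeros((geom.ncells, 0))
    eta = np.full((samples.n_draws, geom.ncells),
                  samples.alpha_flat[:, survey][:, None])
    if Xc.shape[1]:
        eta = eta + samples.beta_flat @ Xc.T
    if samples.zeta_flat is not None:
        eta = eta + samples.zeta_flat
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-eta))
    mean = p.mean(axis=0).reshape(geom.nrows, geom.ncols)
    lo, hi = np.quantile(p, [0.025, 0.975], axis=0)
    year = survey_year if survey_year is not None else (
        samples.survey_years[survey] if survey < len(samples.survey_years)
        else survey)
    return PredictedSurface(
        geometry=geom, mean=mean,
        lower=lo.reshape(geom.nrows, geom.ncols),
        upper=hi.reshape(geom.nrows, geom.ncols),
        survey_year=year)


def _assign_cells(geometry: GridGeometry, regions) -> tuple[np.ndarray, int]:
    """Region index per cell by center-in-polygon; -1 for unassigned."""
    lon, lat = geometry.cell_centers()
    assign = np.full(geometry.ncells, -1, dtype=int)
    pts_x, pts_y = lon.ravel(), lat.ravel()
    for k, (_, poly) in enumerate(regions):
        hit = shapely.contains_xy(poly, pts_x, pts_y) \
            | shapely.contains_xy(poly.boundary, pts_x, pts_y)
        assign[(assign == -1) & hit] = k
    return assign, int((assign == -1).sum())


def aggregate_regions(surfaces, regions, weights: Raster | None = None
                      ) -> pd.DataFrame:
    """Regional and national rate table (deaths per 1000 live births).

    ``surfaces`` is one :class:`PredictedSurface` or a list of them (one
    per survey); rows are region names plus a national row, columns are
    survey years.  Cell weights default to uniform; a population raster
    makes the aggregation population-weighted.  Cells assigned to no
    region are counted and reported via the attribute
    ``df.attrs["unassigned_cells"]``, never silently dropped.
    """
    if isinstance(surfaces, PredictedSurface):
        surfaces = [surfaces]
    if not surfaces:
        raise ValueError("no surfaces to aggregate")
    geom = surfaces[0].geometry
    assign, n_unassigned = _assign_cells(geom, regions)
    if weights is not None:
        if weights.geometry != geom:
            raise ValueError("weight raster grid mismatch")
        w = np.where(weights.mask.ravel(), weights.flat(), 0.0)
        if w.sum() <= 0:
            raise ValueError("weight raster has no positive mass")
    else:
        w = np.ones(geom.ncells)

    names = [name for name, _ in regions]
    table: dict = {}
    for surf in surfaces:
        if surf.geometry != geom:
            raise ValueError("surfaces on different grids")
        p = surf.mean.ravel()
        ok = np.isfinite(p)
        col = {}
        for k, name in enumerate(names):
            sel = (assign == k) & ok
            wk = w[sel]
            col[name] = 1000.0 * float(np.average(p[sel], weights=wk)) \
                if wk.sum() > 0 else np.nan
        sel = (assign >= 0) & ok
        col["national"] = 1000.0 * float(np.average(p[sel], weights=w[sel]))
        table[surf.survey_year] = col
    df = pd.DataFrame(table)
    df = df.loc[names + ["national"]]
    df.attrs["unassigned_cells"] = n_unassigned
    return df


def trend_table(rates: pd.DataFrame,
                stagnation_fraction: float = STAGNATION_FRACTION
                ) -> pd.DataFrame:
    """Per-row trend summary across surveys.

    For each region (row of the rate table, columns ordered by survey):
    absolute and percent change between consecutive surveys and first to
    last, a monotone-non-increasing flag, and a stagnation flag raised
    when the absolute change between the last two surveys is below
    ``stagnation_fraction`` of the earlier value.
    """
    if rates.shape[1] < 2:
        raise ValueError("trend needs at least two surveys")
    cols = list(rates.columns)
    out = []
    for region, row in rates.iterrows():
        vals = row.to_numpy(dtype=float)
        steps = np.diff(vals)
        rec: dict = {"region": region}
        for k in range(len(steps)):
            rec[f"change_{cols[k]}_{cols[k + 1]}"] = steps[k]
            rec[f"pct_change_{cols[k]}_{cols[k + 1]}"] = \
                100.0 * steps[k] / vals[k] if vals[k] != 0 else np.nan
        rec["change_first_last"] = vals[-1] - vals[0]
        rec["pct_change_first_last"] = \
            100.0 * (vals[-1] - vals[0]) / vals[0] if vals[0] != 0 else np.nan
        rec["monotone_decreasing"] = bool(np.all(steps <= 0))
        last_base = vals[-2]
        rec["stagnation"] = bool(
            abs(vals[-1] - last_base) < stagnation_fraction * abs(last_base)
            if last_base != 0 else vals[-1] == 0)
        out.append(rec)
    return pd.DataFrame(out).set_index("region")


def render_maps(surface: PredictedSurface, out_prefix: str | Path,
                dpi: int = 150) -> dict[str, Path]:
    """Write the surface as a 3-band GeoTIFF and a PNG map (per-1000).

    The GeoTIFF carries mean/lower/upper float32 bands with pixel-scale
    and tie-point geo tags; NODATA cells are NaN in the TIFF, rendered
    transparent in the PNG, and excluded from the colour scale.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import tifffile

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    g = surface.geometry
    bands = np.stack([surface.mean, surface.lower, surface.upper]) \
        .astype(np.float32)
    tif_path = out_prefix.with_suffix(".tif")
    cs = float(g.cellsize)
    tifffile.imwrite(
        tif_path, bands, photometric="minisblack",
        extratags=[
            (33550, "d", 3, (cs, cs, 0.0)),  # ModelPixelScale
            (33922, "d", 6, (0.0, 0.0, 0.0, float(g.xllcorner),
                             float(g.yurcorner), 0.0)),  # ModelTiepoint
        ])

    rate = surface.rate_per_1000
    masked = np.ma.masked_invalid(rate)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        masked,
        extent=(g.xllcorner, g.xurcorner, g.yllcorner, g.yurcorner),
        origin="upper", cmap="viridis",
        vmin=float(masked.min()), vmax=float(masked.max()))
    fig.colorbar(im, ax=ax, label="deaths per 1000 live births")
    title = "Predicted under-five mortality"
    if surface.survey_year is not None:
        title += f" ({surface.survey_year})"
    ax.set_title(title)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=dpi)
    plt.close(fig)
    return {"tif": tif_path, "png": png_path}
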