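"""Synthetic DHS-like study generator with known ground truth.

Emulates the inputs of a multi-survey national mortality study: smooth
ecological covariate surfaces (temperature, precipitation, healthcare
access, population density, distance to water, altitude), one latent
spatial field shared across surveys, and cluster-level binomial death
counts.  Defaults are sized to look like a five-survey national series
whose under-five mortality declines from roughly 121 to 59 per 1000
live births, with standardized covariate effects of small-to-moderate
magnitude (|beta| <= ~0.3 per SD).

The altitude surface is built as an affine transform of the temperature
surface plus an orthogonalized smooth residual, so their empirical
correlation equals ``duplicate_pair_corr`` exactly — a near-duplicate
pair that exercises the collinearity screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from shapely.geometry import box

from .model import icar_grid_eigenvalues
from .rasters import (
    CovariateStack,
    GridGeometry,
    Raster,
    write_ascii_grid,
    write_regions,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_COVARIATE_ORDER",
    "generate_covariate_rasters",
    "simulate_gmrf_field",
    "sample_clusters",
    "make_regions",
    "write_fixture",
    "simulate_study",
]

# Screening order: modelled covariates first (report-table order), the
# redundant altitude surface last so the screen drops it, not temperature.
DEFAULT_COVARIATE_ORDER = [
    "access_to_health_facilities",
    "population_density",
    "temperature",
    "precipitation",
    "access_to_cities",
    "distance_to_water",
    "altitude",
]

# Default per-SD effects, magnitudes typical of national ecological studies
# of child mortality (pooled-model scale).
DEFAULT_TRUE_BETA = {
    "access_to_health_facilities": 0.033,
    "population_density": -0.007,
    "temperature": 0.13,
    "precipitation": 0.037,
    "access_to_cities": -0.028,
    "distance_to_water": 0.192,
}

# National per-1000 rates 121 -> 59 across five surveys.
DEFAULT_SURVEY_YEARS = (2000, 2005, 2011, 2016, 2019)
DEFAULT_TRUE_RATES = (121.0, 87.0, 73.0, 60.0, 59.0)

# (base level, amplitude) giving physically plausible raster values.
_COVARIATE_SCALES = {
    "access_to_health_facilities": (120.0, 60.0),   # minutes of travel
    "population_density": (150.0, 120.0),           # persons / km^2
    "temperature": (22.0, 4.0),                     # deg C
    "precipitation": (900.0, 350.0),                # mm / year
    "access_to_cities": (180.0, 90.0),              # minutes of travel
    "distance_to_water": (25.0, 15.0),              # km
    "altitude": (1500.0, 700.0),                    # m
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study."""

    grid_nrows: int = 50
    grid_ncols: int = 50
    cell_size: float = 0.05
    xllcorner: float = 33.0
    yllcorner: float = 3.5
    n_surveys: int = 5
    survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS
    clusters_per_survey: int = 300
    births_min: int = 20
    births_max: int = 60
    true_alpha: tuple[float, ...] | None = None  # default from true rates
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    spatial_sd: float = 0.3
    spatial_range: float = 8.0
    covariate_smoothness: float = 6.0
    duplicate_pair_corr: float = -0.97829
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nrows < 1 or self.grid_ncols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.clusters_per_survey < 1 or self.n_surveys < 1:
            raise ValueError("counts must be positive")
        if not (1 <= self.births_min <= self.births_max):
            raise ValueError("births range must satisfy 1 <= min <= max")
        if self.spatial_sd < 0:
            raise ValueError("spatial_sd must be nonnegative")
        if self.spatial_range <= 0 or self.covariate_smoothness <= 0:
            raise ValueError("range and smoothness must be positive")
        if abs(self.duplicate_pair_corr) > 1:
            raise ValueError("|duplicate_pair_corr| must be <= 1")
        if self.true_alpha is None:
            rates = DEFAULT_TRUE_RATES[: self.n_surveys]
            if len(rates) < self.n_surveys:
                raise ValueError("supply true_alpha for more than 5 surveys")
            self.true_alpha = tuple(float(logit(r / 1000.0)) for r in rates)
        if len(self.true_alpha) != self.n_surveys:
            raise ValueError("true_alpha length must equal n_surveys")
        self.survey_years = tuple(self.survey_years)[: self.n_surveys]
        if len(self.survey_years) != self.n_surveys:
            raise ValueError("survey_years length must cover n_surveys")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            nrows=self.grid_nrows,
            ncols=self.grid_ncols,
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            cellsize=self.cell_size,
        )


@dataclass
class GroundTruth:
    """Generating parameters and the implied per-cell mortality surface."""

    alpha: np.ndarray          # (n_surveys,)
    beta: dict[str, float]
    zeta_grid: np.ndarray      # (nrows, ncols)
    p: np.ndarray              # (n_surveys, nrows, ncols), in (0, 1)

    def national_rates(self) -> np.ndarray:
        """True per-survey national rate per 1000 (uniform cell weights)."""
        return 1000.0 * self.p.reshape(self.p.shape[0], -1).mean(axis=1)


def _smooth_field(rng: np.random.Generator, nrows: int, ncols: int,
                  smoothness: float) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel (SD in cells).

    Rescaled by the kernel's infinite-domain output SD, 1/(2 sqrt(pi)
    smoothness), so the field has SD near 1 at moderate smoothness while
    still flattening to a constant as smoothness grows on a fixed grid.
    """
    noise = rng.standard_normal((nrows, ncols))
    smoothed = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    return smoothed * (2.0 * np.sqrt(np.pi) * smoothness)


def _standardized(grid: np.ndarray) -> np.ndarray:
    sd = grid.std()
    if sd == 0:
        return np.zeros_like(grid)
    return (grid - grid.mean()) / sd


def generate_covariate_rasters(config: SimulationConfig) -> CovariateStack:
    """Generate one smooth raster per named covariate.

    Altitude is a deterministic affine combination of the standardized
    temperature surface and an empirically orthogonalized second smooth
    surface, so corr(temperature, altitude) == duplicate_pair_corr exactly
    (up to floating point) whenever both surfaces are non-degenerate.
    """
    geom = config.geometry
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rasters: dict[str, Raster] = {}
    fields: dict[str, np.ndarray] = {}
    for name in DEFAULT_COVARIATE_ORDER:
        if name == "altitude":
            continue
        fields[name] = _smooth_field(
            rng, geom.nrows, geom.ncols, config.covariate_smoothness)

    t_std = _standardized(fields["temperature"])
    resid = _smooth_field(rng, geom.nrows, geom.ncols, config.covariate_smoothness)
    resid_std = _standardized(resid)
    if t_std.std() > 0:
        # project out the temperature component so the mix is exact
        proj = (resid_std * t_std).mean() / max((t_std**2).mean(), 1e-300)
        resid_std = _standardized(resid_std - proj * t_std)
    rho = config.duplicate_pair_corr
    alt_std = rho * t_std + np.sqrt(max(0.0, 1.0 - rho**2)) * resid_std
    fields["altitude"] = alt_std

    for name in DEFAULT_COVARIATE_ORDER:
        base, amp = _COVARIATE_SCALES[name]
        rasters[name] = Raster(geom, base + amp * fields[name])
    return CovariateStack(rasters)


def simulate_gmrf_field(config: SimulationConfig) -> np.ndarray:
    """Draw a zero-mean GMRF field on the lattice, shaped (nrows, ncols).

    The field is an exact spectral draw from the proper CAR precision
    Q0 + kappa^2 I on the rook lattice (kappa = 1/spatial_range), using
    the DCT-II eigenbasis of the grid Laplacian, then mean-centered and
    scaled so the average marginal SD equals ``spatial_sd``.  The fitted
    prior is the intrinsic (kappa -> 0) member of the same family.
    """
    nr, nc = config.grid_nrows, config.grid_ncols
    if config.spatial_sd == 0:
        return np.zeros((nr, nc))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    kappa2 = 1.0 / config.spatial_range**2
    lam = icar_grid_eigenvalues(nr, nc) + kappa2
    z = rng.standard_normal((nr, nc))
    coefs = z / np.sqrt(lam)
    field = scipy.fft.idctn(coefs, type=2, norm="ortho")
    # average marginal variance = mean over cells of sum_k v_k(i)^2/lam_k
    # = (1/K) sum_k 1/lam_k because the eigenbasis is orthonormal
    avg_var = np.mean(1.0 / lam)
    field = field * (config.spatial_sd / np.sqrt(avg_var))
    return field - field.mean()


def build_truth(config: SimulationConfig, stack: CovariateStack,
                zeta: np.ndarray | None = None) -> GroundTruth:
    """Assemble the true per-cell mortality surfaces from the model."""
    if zeta is None:
        zeta = simulate_gmrf_field(config)
    geom = config.geometry
    eta = np.zeros((config.n_surveys, geom.nrows, geom.ncols))
    for name, b in config.true_beta.items():
        eta += b * _standardized(stack[name].values)[None, :, :]
    eta += zeta[None, :, :]
    eta += np.asarray(config.true_alpha)[:, None, None]
    p = expit(eta)
    return GroundTruth(
        alpha=np.asarray(config.true_alpha, dtype=float),
        beta=dict(config.true_beta),
        zeta_grid=zeta,
        p=p,
    )


def sample_clusters(config: SimulationConfig, rasters: CovariateStack,
                    truth: GroundTruth) -> pd.DataFrame:
    """Draw survey clusters: uniform cells, U{births} sizes, binomial deaths.

    Returns the pipeline's cluster table with columns
    survey_year, cluster_id, lon, lat, births, deaths.
    """
    geom = rasters.geometry
    if truth.p.shape[1:] != (geom.nrows, geom.ncols):
        raise ValueError("truth and rasters are on different grids")
    if geom.ncells == 0:
        raise ValueError("empty grid")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    lon_c, lat_c = geom.cell_centers()
    rows = []
    cid = 0
    for t, year in enumerate(config.survey_years):
        cells = rng.integers(0, geom.ncells, size=config.clusters_per_survey)
        r, c = np.divmod(cells, geom.ncols)
        n = rng.integers(config.births_min, config.births_max + 1,
                         size=config.clusters_per_survey)
        p = truth.p[t, r, c]
        y = rng.binomial(n, p)
        for j in range(config.clusters_per_survey):
            rows.append((year, f"c{cid:06d}", lon_c[r[j], c[j]],
                         lat_c[r[j], c[j]], int(n[j]), int(y[j])))
            cid += 1
    return pd.DataFrame(
        rows, columns=["survey_year", "cluster_id", "lon", "lat",
                       "births", "deaths"])


def make_regions(geometry: GridGeometry, nx: int = 2, ny: int = 2
                 ) -> list[tuple[str, object]]:
    """Partition the grid extent into an nx-by-ny block of rectangles."""
    xs = np.linspace(geometry.xllcorner, geometry.xurcorner, nx + 1)
    ys = np.linspace(geometry.yllcorner, geometry.yurcorner, ny + 1)
    regions = []
    k = 1
    for j in range(ny):
        for i in range(nx):
            regions.append(
                (f"region_{k}", box(xs[i], ys[j], xs[i + 1], ys[j + 1])))
            k += 1
    return regions


def write_fixture(clusters: pd.DataFrame, rasters: CovariateStack,
                  regions: list[tuple[str, object]], out_dir: str | Path,
                  truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a complete file-based study: CSV clusters, .asc rasters,
    GeoJSON regions, and (optionally) the generating truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cpath = out / "clusters.csv"
    clusters.to_csv(cpath, index=False)
    paths["clusters"] = cpath
    for name in rasters.names:
        paths[name] = write_ascii_grid(rasters[name], out / f"{name}.asc")
    paths["regions"] = write_regions(regions, out / "regions.geojson")
    if truth is not None:
        import json

        geom = rasters.geometry
        paths["zeta"] = write_ascii_grid(
            Raster(geom, truth.zeta_grid), out / "true_zeta.asc")
        tpath = out / "truth.json"
        with open(tpath, "w") as fh:
            json.dump(
                {
                    "alpha": list(map(float, truth.alpha)),
                    "beta": truth.beta,
                    "national_rates_per_1000":
                        [float(v) for v in truth.national_rates()],
                },
                fh, indent=2)
        paths["truth"] = tpath
    return paths


def simulate_study(config: SimulationConfig
                   ) -> tuple[pd.DataFrame, CovariateStack, GroundTruth]:
    """Generate clusters, rasters and truth for one synthetic study."""
    stack = generate_covariate_rasters(config)
    truth = build_truth(config, stack)
    clusters = sample_clusters(config, stack, truth)
    return clusters, stack, truth
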