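# geomort

Bayesian geostatistical mapping of under-five mortality from
cluster-survey data.

National household surveys (DHS-style) record, for each geolocated
sampling cluster, how many live births occurred in a window and how
many of those children died before age five. `geomort` turns such
cluster tables, together with ecological covariate rasters
(temperature, precipitation, travel time to care, population density,
distance to water), into smooth mortality surfaces, regional/national
rate tables and trend summaries — the workflow of model-based
geostatistics applied to child mortality. It is aimed at
epidemiologists and biostatisticians who want a transparent,
fully-testable pipeline rather than a black box.

## Model

For cluster *j* with *n<sub>j</sub>* live births, *y<sub>j</sub>*
deaths, survey *t(j)* and lattice cell *c(j)*:

```
y_j ~ Binomial(n_j, p_j)
logit(p_j) = alpha_t(j) + sum_z beta_z x_z,j + zeta_c(j)
```

with standardized covariates *x*, per-survey intercepts *alpha*, and a
zero-mean Gaussian Markov random field *zeta* over the raster lattice
(first-order intrinsic CAR: precision `Q0 / sigma^2` with `Q0` the
rook-graph Laplacian, under a sum-to-zero constraint). Priors are
`Normal(0, 10^2)` on intercepts and coefficients and `Half-Normal(1)`
on the field SD. Inference is by blocked adaptive-Metropolis MCMC with
reparameterising moves for the field/coefficient confounding; model
checking uses leave-one-out conditional predictive ordinates (CPO),
mid-PIT calibration, and WAIC for model comparison. Mortality rates
are reported as `1000 * p` (deaths per 1000 live births). See
`docs/methods.md` for the full account.

A synthetic-data module generates DHS-like multi-survey studies with
known ground truth — smooth correlated covariates (including a
near-duplicate temperature/altitude pair at r ≈ −0.978), a latent
spatial field, and binomial death counts — so every pipeline stage is
testable without restricted microdata.

## Worked example

```python
import geomort as gm
from geomort.preprocessing import standardize_cells

# a small synthetic study: 3 surveys of 300 clusters on a 50 x 50 grid
cfg = gm.SimulationConfig(n_surveys=3, survey_years=(2000, 2005, 2011),
                          clusters_per_survey=300, seed=42)
clusters, rasters, truth = gm.simulate_study(cfg)

design = gm.extract_covariates(clusters, rasters)
screen = gm.correlation_screen(design, threshold=0.8,
                               order=gm.synthetic.DEFAULT_COVARIATE_ORDER)
print(screen.report())
design = gm.standardize(design.subset(screen.retained))
data, years = gm.clusters_to_data(clusters, rasters.geometry)

spec = gm.ModelSpec(covariates=design.names, geometry=rasters.geometry,
                    n_surveys=len(years), spatial=True)
samples = gm.fit(spec, data, design,
                 gm.MCMCConfig(chains=2, iterations=6000, seed=1),
                 survey_years=years,
                 cell_covariates=standardize_cells(
                     rasters.subset(design.names), design))
print(gm.summarize(samples).round(3))

surfaces = [gm.predict_surface(samples, rasters.subset(design.names), spec,
                               design, survey=t, survey_year=y)
            for t, y in enumerate(years)]
rates = gm.aggregate_regions(surfaces, gm.make_regions(rasters.geometry))
print(rates.round(0).astype(int))
```

Output (abridged):

```
retained (6): access_to_health_facilities, population_density, temperature,
              precipitation, access_to_cities, distance_to_water
excluded altitude: |r| = 0.97634 with temperature (r = -0.97634)

                                   mean  lower  upper  significant
alpha_2000                       -1.958 -2.024 -1.885         True
alpha_2005                       -2.371 -2.438 -2.300         True
alpha_2011                       -2.558 -2.640 -2.468         True
beta_distance_to_water            0.215  0.098  0.344         True
beta_temperature                  0.102 -0.034  0.234        False
...
sigma_zeta                        0.359  0.273  0.441        False

          2000  2005  2011
region_1   135    94    79
region_2   106    73    61
region_3   153   107    91
region_4   125    87    73
national   130    90    76
```

The screen drops the redundant altitude surface (it is an engineered
near-duplicate of temperature); the fitted per-survey intercepts give
declining national rates of 130, 90 and 76 deaths per 1000 live births
against generating truth 126, 91, 77; `distance_to_water`
(truth +0.192 per SD) is recovered as the one clearly non-zero
ecological effect (+0.215, 95% CrI 0.098–0.344). `gm.validate(...)`
adds CPO/PIT diagnostics and WAIC for model comparison, and
`gm.render_maps(surface, "out/u5mr_2011")` writes GeoTIFF + PNG maps.

The same pipeline is scriptable from the shell:

```sh
geomort simulate --config config.yaml --out data/ --seed 1
geomort screen   --data data/ --out run/
geomort fit      --data data/ --out run/ --seed 1
geomort report   --data data/ --out report/ --seed 1
```

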