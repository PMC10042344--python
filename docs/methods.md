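# Methods

`geomort` estimates and maps under-five mortality from geolocated
cluster-survey data. This note records the model, the algorithmic and
numerical choices, what the synthetic-data generator does and does not
emulate, and the sizes used by the evaluation scenarios.

## Model

Each survey cluster `j` contributes `n_j` live births and `y_j`
under-five deaths at a known location. The model is a binomial spatial
regression on a regular lon/lat lattice:

    y_j ~ Binomial(n_j, p_j)
    logit(p_j) = alpha_{t(j)} + sum_z beta_z x_{z,j} + zeta_{c(j)}

* `t(j)` — the survey (e.g. year) of cluster `j`; each survey has its
  own intercept, so a multi-survey fit shares `beta` and the field
  while the national level can decline over time.
* `x_{z,j}` — ecological covariates (temperature, precipitation,
  travel time to health facilities and cities, population density,
  distance to water), read off co-registered rasters at the cluster's
  cell and standardized column-wise. Coefficients are therefore
  per-SD effects; the standardization record is stored and reused at
  prediction time.
* `zeta` — a zero-mean Gaussian Markov random field indexed by lattice
  cell `c(j)`; clusters in one cell share the same field value, which
  also makes the likelihood and the prediction surface use a single
  field.

The field prior is a first-order intrinsic CAR (ICAR): the structure
matrix `Q0` is the rook-neighbour graph Laplacian of the grid, the full
precision is `Q0 / sigma_zeta^2`, and a sum-to-zero constraint makes the
intrinsic density proper on the contrast space (rank `K-1` on a
connected lattice of `K` cells). ICAR is the simplest GMRF with the
right qualitative behaviour and admits exact spectral computations on a
grid (the eigenbasis is the orthonormal DCT-II basis; the generalized
log-determinant has a closed form). A Matern/SPDE field would be a
natural extension point but is not implemented.

Priors: `alpha_t, beta_z ~ Normal(0, 10^2)` (weakly informative on the
logit scale), `sigma_zeta ~ Half-Normal(1)` (the field's marginal-scale
SD; mortality log-odds surfaces rarely vary by more than ~1 unit).

An effect is reported "significant" when its equal-tailed 95% credible
interval excludes zero — the usual rule for Bayesian regression tables.
Equal-tailed (not HPD) intervals are used throughout.

## Preprocessing

* **Extraction** is nearest-cell (no interpolation): simple, exactly
  testable, and adequate at km-scale resolution. A point on a cell
  boundary is assigned by round-half-down on the fractional row/col
  index. Clusters outside the extent or on NODATA cells are reported
  by id, never dropped silently.
* **Collinearity screen**: the full Pearson matrix is computed; for
  every pair with `|r| >= 0.8` the covariate appearing *later* in the
  declared order is excluded, with the triggering pair and `r`
  reported. The default threshold 0.8 removes near-duplicate surfaces
  (such as the built-in temperature/altitude pair at r ~ -0.98) while
  keeping moderately correlated predictors (|r| up to ~0.65). The
  rule is deterministic, order-stable and idempotent: screening the
  retained set again excludes nothing. Zero-variance columns are
  excluded with their own reason.

## Inference

The inference engine is the package's own MCMC; correctness is
demonstrated against maximum-likelihood oracles and recovery
simulations rather than against another Bayesian engine. The sampler
is a
blocked adaptive random-walk Metropolis scheme with several
reparameterising moves that target the known weak directions of
latent-Gaussian logistic models:

1. **(alpha, beta) block** — joint random walk. Chains start
   overdispersed around the penalized-likelihood mode (a Newton solve
   with step halving), drawn from `N(mode, 4 H^-1)` where `H` is the
   Fisher information plus prior precision; the initial proposal
   covariance is `H^-1`, later replaced by the running posterior
   covariance (Welford), with the global scale tuned to ~0.28
   acceptance.
2. **Checkerboard field sweeps** — single-site Metropolis vectorized
   over the two colours of the rook lattice (same-colour cells are
   conditionally independent given the rest), step size tuned to ~0.44
   acceptance. After each sweep the field mean is transferred into the
   intercepts (`zeta -= m`, `alpha += m`), which leaves the likelihood
   invariant and enforces the sum-to-zero constraint exactly.
3. **Covariate-surface swaps** — smooth covariates are spatially
   confounded with the field: `beta_z -> beta_z + d` with
   `zeta -> zeta - d * X_z(grid, centred)` changes the likelihood not
   at all (covariate values at cluster cells equal the grid surface),
   so the move is accepted on the prior ratio alone and decorrelates
   `beta` from the field.
4. **Low-frequency mode walks** — the 64 lowest Laplacian eigenmodes
   (exact DCT vectors) are updated one at a time with a compensating
   shift of each survey's intercept (minus the mode's mean over that
   survey's observation cells), mixing the large-scale field/intercept
   directions that single-site sweeps move very slowly.
5. **Joint rescaling** `(zeta, sigma) -> (r zeta, r sigma)` — mixes the
   field amplitude, plus a log-scale random walk on `sigma_zeta`.

Without moves 3–5, split R-hat for intercepts stalls near 1.8–2.2 on
30x30–50x50 grids at realistic data sizes; with them it sits near 1.05
or below. All step sizes adapt only during burn-in (default: first
half), so the retained chain is Markov. Two chains by default; split
R-hat (arviz) is reported per scalar parameter, with a warning and a
`converged` flag when any exceeds 1.05. One master seed
deterministically derives per-chain seeds; identical configuration and
seed reproduce draws bit-for-bit.

Two internal likelihood optimizations (invisible in results): the
combinatorial constant of the binomial pmf is dropped inside the chain
(it cancels in every Metropolis ratio), and observations with identical
(cell, survey, covariate) keys are pooled, since binomials with a common
probability add. The reported pointwise log-likelihood matrix is
computed afterwards per original observation with the full log-pmf,
stably via `log p = -log(1+e^-eta)` so linear predictors of magnitude
40 neither overflow nor truncate to `-inf`.

## Validation

All checks operate on the draws-by-observations matrix `L` of pointwise
binomial log-likelihoods.

* **CPO** uses the harmonic-mean importance identity
  `CPO_i = [ (1/S) sum_s exp(-L[s,i]) ]^-1`, evaluated in log space.
  Harmonic means can be unstable, so each observation is flagged
  unreliable when the effective sample size of its importance weights
  falls below `0.1 S`.
* **PIT** is the mid-PIT for discrete outcomes,
  `P(Y_rep < y_i) + 0.5 P(Y_rep = y_i)`, with the predictive averaged
  under the same leave-one-out weights as CPO. Plain PIT is
  non-uniform for discrete data; the mid correction restores
  approximate uniformity, which is what the calibration check asserts.
* **WAIC** is `-2 (lppd - p_waic)` with
  `lppd = sum_i log mean_s exp(L[s,i])` (log-sum-exp throughout) and
  `p_waic = sum_i Var_s(L[s,i])` with the `S-1` denominator. Model
  comparison sorts ascending by WAIC; ties within 1e-9 go to the model
  with fewer parameters, and reports are checksum-matched to refuse
  cross-dataset comparisons.

## Prediction and reporting

Per draw and cell, `p = inverse-logit(alpha_t + X beta + zeta)`;
surfaces report the cell-wise posterior mean and equal-tailed 95%
interval, scaled to deaths per 1000 live births (`1000 p`). The rate of
a region is the (optionally population-weighted) mean of cell means
over cells whose centers fall in the region polygon; the national rate
is the same mean over all assigned cells, so it equals the
weight-combined regional rates by construction. Cells outside every
region are counted and reported, not dropped. Rounding to integer
per-1000 happens only when tables are written.

This equates the mortality rate with the binomial proportion — the
model's own scale. The DHS synthetic-cohort life-table estimator of
U5MR is a different quantity and is deliberately out of scope; fitted
rates are comparable across surveys and regions within this model, but
are not life-table U5MRs.

Trend summaries give absolute and percent changes between consecutive
surveys and first-to-last, a monotone-non-increasing flag, and a
stagnation flag raised when the last inter-survey change is below 5% of
the earlier value.

## Synthetic data

The generator emulates a multi-survey national mortality study with
known truth, so every stage is testable without restricted microdata:

* **Covariates**: white noise smoothed by a Gaussian kernel
  (`covariate_smoothness` = kernel SD in cells, default 6), rescaled by
  the kernel's theoretical output SD and mapped to plausible physical
  ranges (temperature ~22±4 C, precipitation ~900±350 mm, ...). As
  smoothness grows on a fixed grid the surfaces flatten toward
  constants. The altitude surface is an exact affine mix of the
  standardized temperature surface and an orthogonalized smooth
  residual, so corr(temperature, altitude) equals
  `duplicate_pair_corr` (default -0.97829) to machine precision —
  a built-in near-duplicate pair for the screen.
* **Field**: an exact spectral draw (DCT eigenbasis) from the proper
  CAR precision `Q0 + I / spatial_range^2` on the same rook lattice,
  mean-centred and scaled so the average marginal SD equals
  `spatial_sd` (default 0.3, range 8 cells). The fitting prior is the
  intrinsic (infinite-range) member of the same family, built by the
  same precision constructor, so simulation and inference share one
  lattice structure.
* **Truth**: per-survey intercepts default to the logits of a national
  series declining from 121 to 59 deaths per 1000 live births across
  five surveys; standardized effects default to small-to-moderate
  magnitudes (from -0.007 to +0.192 per SD). Per-cell true
  probabilities are `inverse-logit(alpha_t + X beta + zeta)`.
* **Clusters**: uniform-random cells, cluster sizes U{20..60} births
  (typical DHS cluster birth counts), deaths binomial at the cell's
  true probability; default 300 clusters per survey. Everything is
  deterministic given the seed.

Deliberately **not** emulated: DHS two-stage sampling and design
weights, urban oversampling, GPS displacement, non-uniform cluster
placement, covariate measurement error, and the life-table outcome
definition. Passing tests therefore demonstrate correctness of the
method under its own assumptions — exactly the regime where parameter
recovery is well-posed — not robustness to those real-data features.

## Evaluation scenario sizes

The scenarios in `geomort.scenarios` (driven by `scripts/acceptance.py`
and the end-to-end tests) are sized for statistical power on one CPU:

* GLM limit: 500 clusters, one survey, no field; posterior mean vs an
  independent IRLS fit (statsmodels), agreement well under 0.05.
* Calibration: 50 replicates x 2000 clusters; per-parameter 95%
  interval coverage and posterior-mean bias.
* WAIC selection: 20 simulations x 400 clusters, generating model vs
  itself plus a pure-noise covariate, 8000-iteration chains (shorter
  chains occasionally leave one fit unconverged, which corrupts
  `p_waic` and hence the comparison).
* CPO: a 12-cluster, one-covariate study; harmonic-mean CPO against
  exact refit-leave-one-out predictive densities (13 separate fits).
* PIT: 1000 clusters under the true model; KS distance to uniform.
* End-to-end trend: 5 surveys x 8000 clusters on a 50x50 grid with the
  shared spatial field, 12000-iteration chains. The final step of the
  default truth series (60 -> 59 per 1000) is a ~1.6% change; resolving
  its direction and the stagnation flag requires the standard error of
  an estimated inter-survey change to be well under ~1 per 1000, which
  sets the 8000-cluster size (se ~ 0.6 at ~40 births/cluster).

## Known limitations

* ICAR on the raster lattice, not a continuous Matern field; spatial
  resolution is the cell size, and `zeta` is piecewise constant.
* One shared field across surveys in pooled fits; no space-time
  interaction.
* Random-walk-based MCMC: wall-clock minutes for ~10^4 clusters on a
  50x50 grid; much larger grids would want a sparse-linear-algebra
  sampler.
* The harmonic-mean CPO estimator degrades for highly influential
  observations (hence the ESS flag).
* Aggregated (ecological) covariate effects: coefficients describe
  cluster-level association, not individual-level risk.
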