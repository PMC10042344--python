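import warnings

import numpy as np
import pytest

import geomort as gm
from geomort.synthetic import DEFAULT_COVARIATE_ORDER


@pytest.fixture(scope="session")
def small_config():
    return gm.SimulationConfig(
        grid_nrows=20, grid_ncols=20, n_surveys=2,
        survey_years=(2000, 2005), clusters_per_survey=120, seed=7)


@pytest.fixture(scope="session")
def small_study(small_config):
    return gm.simulate_study(small_config)


def prepare(clusters, stack, threshold=0.8):
    """Standard pipeline front-end: extract, screen, standardize, map."""
    design = gm.extract_covariates(clusters, stack)
    result = gm.correlation_screen(design, threshold=threshold,
                                   order=DEFAULT_COVARIATE_ORDER)
    design = gm.standardize(design.subset(result.retained))
    data, years = gm.clusters_to_data(clusters, stack.geometry)
    return design, result, data, years


@pytest.fixture(scope="session")
def small_fit(small_study):
    """A quick non-spatial posterior on the small synthetic study."""
    clusters, stack, truth = small_study
    design, result, data, years = prepare(clusters, stack)
    spec = gm.ModelSpec(covariates=design.names, geometry=stack.geometry,
                        n_surveys=len(years), spatial=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = gm.fit(spec, data, design,
                         gm.MCMCConfig(chains=2, iterations=3000, seed=11),
                         survey_years=years)
    return samples, spec, design, data


def make_samples(alpha, beta=None, zeta=None, sigma=None,
                 covariates=(), survey_years=(2000,), loglik=None):
    """Hand-crafted PosteriorSamples for unit tests (one chain)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim == 2:
        alpha = alpha[None]
    S = alpha.shape[1]
    beta = np.zeros((1, S, 0)) if beta is None else np.asarray(beta, float)[None]
    return gm.PosteriorSamples(
        alpha=alpha, beta=beta,
        zeta=None if zeta is None else np.asarray(zeta, float)[None],
        sigma=None if sigma is None else np.asarray(sigma, float)[None],
        loglik=np.zeros((S, 0)) if loglik is None else loglik,
        covariates=list(covariates), survey_years=list(survey_years))
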