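import numpy as np
import pandas as pd
import pytest

from huntniche import association, spatial, synthetic
from huntniche.model import DEFAULT_TERMS


def small_config(**overrides):
    """Fast study-shaped config for integration-level tests."""
    defaults = dict(seed=0, n_days=60, relocations_per_day=60,
                    scans_per_day=8, hunt_rate_per_day=2.0)
    defaults.update(overrides)
    return synthetic.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def recovery_dataset():
    """One simulated study (~500 hunts) with the default ground truth,
    plus analysis-side covariates, shared across model tests."""
    cfg = synthetic.SimulationConfig(seed=42, n_days=125,
                                     relocations_per_day=60,
                                     scans_per_day=10, hunt_rate_per_day=4.0)
    res = synthetic.simulate(cfg)
    cov = analysis_covariates(res)
    return cfg, res, cov


def analysis_covariates(result):
    """Recompute per-hunt covariates from raw tables, as the pipeline does."""
    usage = spatial.usage_difference(result.hunts, result.uds)
    years = sorted(pd.to_datetime(result.scans["timestamp"]).dt.year.unique())
    sri = {int(y): association.compute_sri(result.scans, int(y))
           for y in years}
    return association.hunt_party_covariates(
        result.hunts, result.scans, result.individuals, sri,
        usage_scores=usage)


def grid_posterior_2param(x, y_is_one, prior_df=3.0, prior_scale=2.5,
                          half_width=6.0, n_grid=401):
    """Dense grid integration of the 1-predictor, 2-category posterior.

    Independent oracle for the MCMC sampler: returns posterior mean and sd
    of (intercept, slope) under the same Student-t priors.
    """
    b0 = np.linspace(-half_width, half_width, n_grid)
    b1 = np.linspace(-half_width, half_width, n_grid)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    eta = B0[..., None] + B1[..., None] * np.asarray(x)
    loglik = (eta[..., y_is_one].sum(axis=-1)
              - np.log1p(np.exp(eta)).sum(axis=-1))
    logprior = sum(-0.5 * (prior_df + 1)
                   * np.log1p(b * b / (prior_df * prior_scale ** 2))
                   for b in (B0, B1))
    logpost = loglik + logprior
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = np.array([(w * B0).sum(), (w * B1).sum()])
    sd = np.sqrt(np.array([(w * (B0 - mean[0]) ** 2).sum(),
                           (w * (B1 - mean[1]) ** 2).sum()]))
    return mean, sd


def model_frame(cov):
    """Covariate table restricted to the model predictors + prey."""
    cols = [c for c in DEFAULT_TERMS if c in cov.columns] + ["prey"]
    return cov[cols].dropna().reset_index(drop=True)
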