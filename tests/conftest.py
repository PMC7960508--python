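"""Shared fixtures: synthetic panels and fitted posteriors.

The expensive objects (MCMC fits) are session-scoped so the suite pays
for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from citymort.ages import collapse_to_ddm
from citymort.bayes import ModelConfig, ModelData, fit_mortality_model
from citymort.completeness import CensusPair
from citymort.synthetic import (
    make_panel_truths,
    make_schedule,
    simulate_deaths,
    stable_population,
)

SEXES = ("F", "M")


def stationary_fixture(sex="F", total=1e6, growth=0.0, thin=1.0):
    """Stable-population census pair plus window deaths that satisfy the
    death-distribution balance identities by construction."""
    sched = make_schedule(1.0, sex=sex)
    n1 = stable_population(sched, growth, total)
    n2 = n1 * np.exp(growth * 5.0)
    deaths17 = 5.0 * np.sqrt(n1 * n2) * sched.rates
    census = CensusPair.from_17(n1, n2, 2012.0, 2017.0)
    return census, collapse_to_ddm(deaths17) * thin, sched


@pytest.fixture(scope="session")
def small_truths():
    return make_panel_truths(2, 5, seed=2, mean_population=300_000)


@pytest.fixture(scope="session")
def small_panel(small_truths):
    return simulate_deaths(small_truths, seed=7)


@pytest.fixture(scope="session")
def calibration_fit(small_truths):
    """Known-truth calibration setup: y ~ Pois(c n lambda) with c drawn
    from its own Beta prior, fitted at the scaled-down MCMC schedule."""
    rng = np.random.default_rng(42)
    truths = small_truths
    lam_true = np.stack(
        [np.stack([t.schedules[s].rates for s in SEXES], axis=-1) for t in truths]
    )
    n = np.stack(
        [np.stack(
            [5 * np.sqrt(t.base_population[s] ** 2 * np.exp(t.growth_rate * 5))
             for s in SEXES], axis=-1)
         for t in truths]
    )
    phi = np.array([[t.coverage[s] for s in SEXES] for t in truths])
    K = phi * (1 - phi) / 0.0009 - 1
    pa, pb = K * phi, K * (1 - phi)
    c_true = rng.beta(pa, pb)
    y = rng.poisson(c_true[:, None, :] * n * lam_true).astype(float)
    data = ModelData(
        y=y, n=n, country_idx=np.array([t.country_id for t in truths]) == "C2",
        city_ids=[t.city_id for t in truths], country_ids=["C1", "C2"],
        prior_alpha=pa, prior_beta=pb,
    )
    data.country_idx = data.country_idx.astype(int)
    cfg = ModelConfig(burn_in=2_000, iterations=4_000, thin=4, seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        posterior = fit_mortality_model(data, cfg)
    return dict(posterior=posterior, lam_true=lam_true, c_true=c_true,
                truths=truths, y=y, n=n)


@pytest.fixture(scope="session")
def end_to_end(small_truths, small_panel):
    """Full chain on the standard small panel: preprocess, completeness
    ensemble, Bayesian fit, posterior life expectancies."""
    from citymort.bayes import model_data_from_frames
    from citymort.completeness import completeness_table
    from citymort.lifetables import le_table
    from citymort.preprocess import preprocess

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean = preprocess(small_panel.deaths, seed=11)
        comp = completeness_table(small_panel.census, clean)
        data = model_data_from_frames(clean, small_panel.census, comp)
        # longer schedule than the calibration fixture: the end-to-end
        # check reads 2.5% tail quantiles, which need the extra effective
        # sample size
        cfg = ModelConfig(burn_in=4_000, iterations=12_000, thin=12, seed=13)
        posterior = fit_mortality_model(data, cfg)
        table, draws = le_table(
            posterior["lam"].values,
            [str(c) for c in posterior.city.values],
            [str(c) for c in posterior.city_country.values],
            [str(s) for s in posterior.sex.values],
            return_draws=True,
        )
    return dict(panel=small_panel, truths=small_truths, clean=clean,
                completeness=comp, posterior=posterior,
                le_table=table, le_draws=draws)
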