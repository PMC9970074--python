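"""Shared fixtures: small synthetic studies and fast MCMC settings.

Session-scoped fixtures fit the nine node-wise models once on a compact
continuous dataset so the network and prediction tests can share them.
"""

import numpy as np
import pytest

from sdmnet import (
    GeneratorConfig,
    McmcConfig,
    fit_all_nodes,
    build_physician_network,
    build_population_network,
    sample_true_model,
    simulate_ratings,
    simulate_observer_scores,
    aggregate_observer,
)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for tests: 2 x (1300-300)/2 = 1000 draws."""
    return McmcConfig(n_chains=2, iterations=1300, burn_in=300, thinning=2, seed=101)


@pytest.fixture(scope="session")
def small_model():
    cfg = GeneratorConfig(
        n_physicians=12,
        n_recorded=12,
        instrument_coverage={"OPTION-12": 11, "OPTION-5": 12, "4HCS": 11},
        heterogeneity=0.08,
    )
    return sample_true_model(cfg, seed=314)


@pytest.fixture(scope="session")
def small_ratings(small_model):
    return simulate_ratings(small_model, 25, discretize=False, seed=315)


@pytest.fixture(scope="session")
def small_fits(small_ratings, fast_mcmc):
    return fit_all_nodes(small_ratings, mcmc=fast_mcmc)


@pytest.fixture(scope="session")
def small_networks(small_fits, small_ratings):
    pids = sorted(small_ratings["physician_id"].unique())
    return {
        pid: build_physician_network(small_fits, small_ratings, pid)
        for pid in pids
    }


@pytest.fixture(scope="session")
def small_population(small_fits, small_ratings):
    return build_population_network(small_fits, small_ratings)


@pytest.fixture(scope="session")
def small_scores(small_model):
    obs = simulate_observer_scores(small_model, seed=316)
    return aggregate_observer(obs)
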