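"""Shared simulation runs for the test suite.

The expensive replicated runs are session-scoped so several tests can
interrogate the same Monte-Carlo experiment: a no-bias scenario with
heterogeneity (unbiasedness, MSE and power orderings), null scenarios at
two heterogeneity levels (type-I error behavior), and a reduced-replicate
Bayesian run with shortened chains.
"""

import math
import warnings

import pytest

from nmasim import MCMCSettings, ScenarioConfig, run_scenario

# Shortened chains for replicated desk-scale Bayesian runs; recorded here
# as the harness parameter they are.
SHORT_MCMC = MCMCSettings(burn_in=300, iterations=900, thin=1, chains=1, seed=0)


@pytest.fixture(scope="session")
def nobias_scenario():
    """3x20 studies, tau2 = 0.05, baseline 20%, OR12 = 0.8, OR13 = 0.6, no bias."""
    return ScenarioConfig(
        n_studies_12=20,
        n_studies_13=20,
        n_studies_23=20,
        tau2=0.05,
        true_logor_13=math.log(0.6),
        seed=101,
        n_reps=500,
        name="nobias",
    )


@pytest.fixture(scope="session")
def nobias_run_freq(nobias_scenario):
    """Frequentist methods on the no-bias scenario, both pooling models."""
    return run_scenario(
        nobias_scenario,
        methods=("DTC", "AITC", "CFMTC"),
        models=("fixed", "random"),
    )


@pytest.fixture(scope="session")
def nobias_run_bayes(nobias_scenario):
    """Bayesian methods on the no-bias scenario at reduced replicates."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_scenario(
            nobias_scenario,
            methods=("CBMTC", "RIBMTC", "IBMA"),
            models=("random",),
            mcmc=SHORT_MCMC,
            n_reps=100,
        )


def _null_scenario(tau2, seed):
    # OR13 = OR12 makes the true 2-3 log OR exactly zero.
    return ScenarioConfig(
        tau2=tau2,
        true_logor_13=math.log(0.8),
        seed=seed,
        n_reps=500,
        name=f"null_tau{tau2}",
    )


@pytest.fixture(scope="session")
def null_run_tau0():
    return run_scenario(_null_scenario(0.0, 211), models=("fixed", "random"))


@pytest.fixture(scope="session")
def null_run_tau15():
    return run_scenario(_null_scenario(0.15, 223), models=("fixed", "random"))
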