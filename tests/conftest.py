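import numpy as np
import pytest

from mangrove_carbon.model import FitConfig, ParameterDraw, fit_posterior
from mangrove_carbon.pairing import StratumSpec
from mangrove_carbon.synthetic import SyntheticConfig, simulate_dataset, simulate_ratios

#: the parameter-recovery truth exercised throughout the fitting tests
TRUTH = ParameterDraw(rmax=0.75, beta0=-3.0, beta1=1.5, sigma=0.2)


def truth_config(seed: int = 42) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed, true_params={"agb": TRUTH, "bgb": TRUTH, "soil": TRUTH}
    )


@pytest.fixture(scope="session")
def truth_obs():
    """250 belowground-biomass ratio observations simulated from TRUTH."""
    obs, _ = simulate_ratios(truth_config(), "bgb")
    assert len(obs) == 250
    return obs


@pytest.fixture(scope="session")
def truth_fit(truth_obs):
    """Posterior for the TRUTH dataset (shared: fitting is the slow step)."""
    return fit_posterior(truth_obs, cfg=FitConfig(seed=7))


@pytest.fixture(scope="session")
def prior_fit():
    """Empty-data fit: the posterior is the prior itself."""
    return fit_posterior([], cfg=FitConfig(seed=5), stratum=StratumSpec("bgb", "all"))


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset plus its truth record."""
    return simulate_dataset(SyntheticConfig(seed=9))
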