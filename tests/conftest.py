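import numpy as np
import pytest

from roadmoss import (
    McmcConfig,
    ModelParameters,
    SiteRecord,
    default_truth,
    fit_model,
    generate_design,
    simulate_concentrations,
)


@pytest.fixture(scope="session")
def default_design():
    """The default 110-location study design with its sampling plan."""
    return generate_design(seed=0)


@pytest.fixture(scope="session")
def zn_dataset(default_design):
    """One synthetic Zn 2006 dataset simulated from the default truth."""
    sites, plan = default_design
    obs = simulate_concentrations(sites, plan, default_truth("Zn", 2006),
                                  element="Zn", year=2006, seed=101)
    return sites, obs


@pytest.fixture(scope="session")
def zn_fit(zn_dataset):
    """A reduced-schedule fit of the synthetic Zn 2006 dataset, with latent
    draws, shared across tests that only need a plausible posterior."""
    sites, obs = zn_dataset
    config = McmcConfig(n_chains=2, n_iterations=600, seed=7)
    return fit_model(obs, sites, config)


@pytest.fixture
def small_sites():
    """Five hand-placed sites spanning near-road to reference distances."""
    coords = [(0.0, 30.0, "north"), (500.0, -120.0, "south"),
              (1500.0, 900.0, "north"), (3000.0, -2500.0, "south"),
              (9000.0, 4000.0, "north")]
    return [SiteRecord(f"S{i}", x, abs(y), distance_to_road=abs(y), side=side)
            for i, (x, y, side) in enumerate(coords)]


def make_params(beta=(5.0, -0.5, -0.3, 0.05), s0=0.05, s1=0.1, s2=0.3, theta=2000.0):
    return ModelParameters(beta=np.array(beta), sigma0_sq=s0, sigma1_sq=s1,
                           sigma2_sq=s2, theta=theta)
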