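import numpy as np
import pytest

from mestweb.model import CommunityState, ModelParams, four_species_params


@pytest.fixture
def fig2_params() -> ModelParams:
    """Four-species configuration of the bifurcation/chaos study."""
    return four_species_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_state(rng: np.random.Generator, n: int = 1,
                 biomass_hi: float = 3.0) -> CommunityState:
    """Random valid community state: positive biomasses, efforts on the
    simplex with a strictly positive remainder for C."""
    b = rng.uniform(0.01, biomass_hi, n + 3)
    theta_full = rng.dirichlet(np.ones(n + 2))
    return CommunityState(F0=b[0], F=b[1:1 + n], C=b[n + 1], P=b[n + 2],
                          theta=theta_full[:-1])
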