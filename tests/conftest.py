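import numpy as np
import pytest

from ecoevo import IntegrationSpec, make_params


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220809)


@pytest.fixture(scope="session")
def fig1a_params():
    """Bistable mutation-free parameter set (extinction + defector-free)."""
    return make_params(0.38, 1.1, 0.85, 0.30, 0.0, 0.36, 0.25)


@pytest.fixture(scope="session")
def fig1d_params():
    """Bistable parameter set with mutation (extinction + coexistence)."""
    return make_params(0.30, 1.1, 0.85, 0.30, 0.02, 0.30, 0.20)


@pytest.fixture(scope="session")
def sweep_base_params():
    """Base point of the one-parameter sweeps (50% mutation)."""
    return make_params(0.25, 1.1, 0.85, 0.65, 0.5, 0.75, 0.25)


@pytest.fixture(scope="session")
def fast_spec():
    """Short integration budget for unit tests (total time 200)."""
    return IntegrationSpec(max_steps=20_000, record_every=10)


def sample_params(rng, mu=None, sigma_free=False, unchecked=False):
    """One random parameter set drawn uniformly from the legal domains."""
    return make_params(
        xi=rng.uniform(0.02, 1.0),
        beta=rng.uniform(1.01, 1.99),
        eta=rng.uniform(0.01, 0.99),
        p=rng.uniform(0.0, 1.0),
        mu=rng.uniform(0.0, 1.0) if mu is None else mu,
        sigma1=0.0 if sigma_free else rng.uniform(0.0, 1.0),
        sigma2=0.0 if sigma_free else rng.uniform(0.0, 1.0),
        unchecked=unchecked,
    )


def sample_state(rng):
    """Uniform point on the simplex x, y >= 0, x + y <= 1."""
    x = rng.uniform(0.0, 1.0)
    y = rng.uniform(0.0, 1.0 - x)
    return x, y
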