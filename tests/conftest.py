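import numpy as np
import pytest

import antimix as am


@pytest.fixture(scope="session")
def small_sim():
    """Small 4-alternative panel with 3 mixed constants (I=40, T=10)."""
    return am.simulate_panel(
        am.SimSpec(n_individuals=40, n_situations=10, seed=1)
    )


@pytest.fixture(scope="session")
def small_params(small_sim):
    return am.params_from_moments(small_sim)


def make_config(n_dims=3, r=96, i=40, mode="none", **kw):
    return am.DrawConfig(
        n_dims=n_dims,
        primes=am.CANONICAL_PRIMES[:n_dims],
        draws_per_individual=r,
        n_individuals=i,
        antithetic_mode=mode,
        **kw,
    )


@pytest.fixture(scope="session")
def config_factory():
    return make_config
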