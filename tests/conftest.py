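import numpy as np
import pytest

from songlearn import (
    HVCCode,
    NetworkParams,
    NetworkState,
    make_hvc_code,
    make_template_song,
)


@pytest.fixture
def small_params() -> NetworkParams:
    """A 40/50/20 network: the fast analogue of the full protocol."""
    return NetworkParams(n_hvc=40, n_ra=50, n_steps=20)


@pytest.fixture
def small_code(small_params) -> HVCCode:
    return make_hvc_code(small_params.n_hvc, small_params.n_steps)


@pytest.fixture
def small_template(small_params):
    return make_template_song(small_params.n_steps, rng_seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_state(params: NetworkParams, rng: np.random.Generator,
                 scale: float = 0.1) -> NetworkState:
    """A NetworkState with O(scale) random weights (not the training init)."""
    return NetworkState(
        m_weights=rng.normal(0, scale, (params.n_ra, params.n_hvc)),
        w_weights=rng.normal(0, scale, (params.n_ra, params.n_hvc)),
        a_readout=rng.normal(0, 1, (2, params.n_ra)),
    )
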