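import numpy as np
import pytest

from rloopwalk import (
    ModelParams,
    TargetSpec,
    build_landscape,
    landscape_to_rates,
)


@pytest.fixture
def params():
    """Best-fit parameter set of the locked-formation experiments."""
    return ModelParams()


@pytest.fixture
def flat_params():
    """Bias-free parameters giving the flat landscape of a matched target."""
    return ModelParams(k_step=1900.0, dG_ini=8.5, dG_bias_intrinsic=0.0)


def make_chain(target: TargetSpec, params: ModelParams, torque: float = 0.0,
               **kw):
    ls = build_landscape(target, params, torque)
    return ls, landscape_to_rates(ls, target, params, **kw)


@pytest.fixture
def chain_factory():
    return make_chain


def random_chain(rng: np.random.Generator, n: int = 8):
    """A random positive-rate birth-death chain for property tests."""
    from rloopwalk import RateChain

    up = rng.uniform(0.5, 2000.0, n)
    down = rng.uniform(0.5, 2000.0, n)
    return RateChain(up=up, down=down, torque=0.0, absorbing_top=False)
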