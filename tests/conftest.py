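import numpy as np
import pytest

from ca1sim.params import (
    DynamicsParams,
    GeometryParams,
    KernelParams,
    ModelParams,
    PlasticityParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A compact network (12x12 pyramidal, 4x4 interneurons, 12x12 input)
    for fast unit tests of the dynamics and plasticity machinery."""
    return ModelParams(
        geometry=GeometryParams(
            p_rows=12, p_cols=12, i_rows=4, i_cols=4, input_rows=12, input_cols=12
        )
    )


@pytest.fixture
def protocol_params():
    """The scaled network used for protocol-level tests (20x20 map, 7x7
    interneurons, 20x20 stimuli)."""
    from ca1sim.params import scaled_params

    return scaled_params(side=20, i_side=7)
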