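import numpy as np
import pytest

from quickdwi.phantom import Compartment, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_spec():
    """One centred ellipse lesion inside a healthy-tissue disc on 64x64."""
    return PhantomSpec(
        grid_shape=(64, 64),
        compartments=(
            Compartment(
                label="tissue",
                shape="ellipse",
                center=(32.0, 32.0),
                radii=(24.0, 24.0),
                s0=1000.0,
                adc=1.4e-3,
            ),
            Compartment(
                label="lesion",
                shape="ellipse",
                center=(32.0, 32.0),
                radii=(8.0, 8.0),
                s0=1500.0,
                adc=0.7e-3,
                is_lesion=True,
            ),
        ),
        background_s0=0.0,
        seed=7,
    )


@pytest.fixture
def simple_gt(simple_spec):
    return generate_phantom(simple_spec)
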