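import numpy as np
import pytest

from cordmpm.phantom import (B1FieldSpec, NoiseSpec, PhantomSpec,
                             simulate_subject)


@pytest.fixture(scope="session")
def quiet_spec():
    """Noiseless, motion-free phantom with a flat transmit field."""
    return PhantomSpec(
        noise=NoiseSpec(model="none"),
        motion={},
        b1=B1FieldSpec(gradient_percent_per_mm=(0.0, 0.0, 0.0)),
    )


@pytest.fixture(scope="session")
def quiet_subject(quiet_spec):
    return simulate_subject(quiet_spec)


@pytest.fixture(scope="session")
def small_quiet_subject():
    """Down-scaled noiseless phantom for interpolation-heavy tests."""
    spec = PhantomSpec(
        shape=(32, 32, 12),
        noise=NoiseSpec(model="none"),
        motion={},
        b1=B1FieldSpec(gradient_percent_per_mm=(0.0, 0.0, 0.0)),
    )
    return simulate_subject(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
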