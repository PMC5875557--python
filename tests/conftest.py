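import numpy as np
import pytest

from dose4d import PhantomSpec, build_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(20160308)


@pytest.fixture(scope="session")
def moving_spec():
    """Desk-scale moving phantom: 8 mm sphere, 6 mm craniocaudal excursion."""
    return PhantomSpec(
        shape=(24, 24, 16),
        spacing=(2.0, 2.0, 3.0),
        radius_mm=8.0,
        amplitude_mm=(0.0, 0.0, 6.0),
        n_phases=10,
        hu_noise_sd=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def static_spec():
    """Same phantom with zero motion (identity scenario)."""
    return PhantomSpec(
        shape=(24, 24, 16),
        spacing=(2.0, 2.0, 3.0),
        radius_mm=8.0,
        amplitude_mm=(0.0, 0.0, 0.0),
        n_phases=10,
        hu_noise_sd=5.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def moving_phantom(tmp_path_factory, moving_spec):
    return build_phantom(moving_spec, tmp_path_factory.mktemp("phantom_moving"))


@pytest.fixture(scope="session")
def static_phantom(tmp_path_factory, static_spec):
    return build_phantom(static_spec, tmp_path_factory.mktemp("phantom_static"))
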