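import numpy as np
import pytest

from lvfast import PhantomSpec, VoxelGeometry, generate_phantom, run_pipeline


def small_spec(**overrides) -> PhantomSpec:
    """A fast low-resolution phantom for unit tests (FOV preserved)."""
    defaults = dict(
        n_slices=8,
        n_phases=20,
        matrix=128,
        geometry=VoxelGeometry(2.8, 2.8, 10.0),
        edv_target=150.0,
        ef_target=0.60,
        noise_sigma=5.0,
        rng_seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def standard_phantom():
    """The standard study phantom: 10 slices x 20 phases on a 256 matrix,
    EF target 60%, 150° basal opening with a bright distractor, noise at 5%
    of blood intensity."""
    spec = PhantomSpec(rng_seed=20)
    return (spec, *generate_phantom(spec))


@pytest.fixture(scope="session")
def standard_run(standard_phantom):
    """Pipeline result on the standard phantom (shared across tests)."""
    _spec, stack, truth = standard_phantom
    return run_pipeline(stack), truth


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise-free small phantom with a closed myocardial ring everywhere."""
    spec = small_spec(
        noise_sigma=0.0, basal_open_slices=0, basal_open_angle_deg=0.0,
        distractor=False,
    )
    return (spec, *generate_phantom(spec))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
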