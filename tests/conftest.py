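import numpy as np
import pytest

from plexuq import ImageGrid, PhantomSpec, SampleStack, ScalarVolume


@pytest.fixture
def grid16():
    return ImageGrid.from_spacing((16, 16, 16))


@pytest.fixture
def random_stack(grid16):
    """Factory for random probability stacks on the 16^3 grid."""

    def make(n_samples=10, seed=0, members=1):
        rng = np.random.default_rng(seed)
        k_per = n_samples // members
        samples = {
            (m, k): rng.random(grid16.shape)
            for m in range(1, members + 1)
            for k in range(1, k_per + 1)
        }
        return SampleStack(grid=grid16, samples=samples)

    return make


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A 32^3 phantom for tests where geometry detail is not the point."""
    return PhantomSpec(
        shape=(32, 32, 32),
        ventricle_centers=((10.0, 16.0, 16.0), (22.0, 16.0, 16.0)),
        ventricle_semiaxes=(4.5, 6.5, 8.0),
        plexus_radius=1.3,
    )


@pytest.fixture
def constant_volume(grid16):
    def make(value, probability=True):
        return ScalarVolume(
            grid=grid16, values=np.full(grid16.shape, float(value)), is_probability=probability
        )

    return make
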