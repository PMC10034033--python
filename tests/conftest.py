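import numpy as np
import pytest

from perfmap.phantom import PhantomSpec, make_phantom


def small_spec(noise_sd=0.0, seed=0, n_frames=32, **kw):
    """A 24x24x2 phantom that keeps voxel-wise tests fast."""
    regions = {
        "normal": {"kind": "cylinder", "center_mm": (36.0, 36.0),
                   "radius_mm": 30.0},
        "artery": {"kind": "cylinder", "center_mm": (36.0, 16.0),
                   "radius_mm": 6.0},
        "core": {"kind": "sphere", "center_mm": (26.0, 48.0, 5.0),
                 "radius_mm": 8.0},
        "penumbra": {"kind": "shell", "center_mm": (26.0, 48.0, 5.0),
                     "inner_radius_mm": 8.0, "outer_radius_mm": 14.0},
    }
    return PhantomSpec(grid_shape=(24, 24, 2), voxel_spacing=(3.0, 3.0, 5.0),
                       n_frames=n_frames, noise_sd=noise_sd, seed=seed,
                       regions=regions, **kw)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return make_phantom(PhantomSpec(noise_sd=0.0))


@pytest.fixture(scope="session")
def small_noiseless_bundle():
    return make_phantom(small_spec(noise_sd=0.0))


@pytest.fixture(scope="session")
def small_noisy_bundle():
    return make_phantom(small_spec(noise_sd=2.0, seed=7))


@pytest.fixture(scope="session")
def noisy_bundle():
    return make_phantom(PhantomSpec(noise_sd=2.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
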