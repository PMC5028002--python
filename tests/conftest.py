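import numpy as np
import pytest

from corticomap.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def slab_spec():
    """Noiseless flat-slab phantom: fully analytic ground truth."""
    return PhantomSpec(
        nx=80, ny=80, extent=(24.0, 24.0), thickness=2.5,
        fold_amplitude=0.0, patch_radius=4.0, patch_contrast=2.0,
        noise_sd=0.0, bias_amplitude=0.0, cluster_offset=(2.0, 0.0, 0.0),
        n_frames=120, stimulus_period=20.0, seed=11,
    )


@pytest.fixture
def slab_phantom(slab_spec):
    # function-scoped: renders record truth in place, so tests must not share
    return make_phantom(slab_spec)


@pytest.fixture(scope="session")
def noisy_spec():
    """Folded sheet with noise and bias at the default study levels."""
    return PhantomSpec(
        nx=80, ny=80, extent=(24.0, 24.0), patch_radius=4.0,
        fold_amplitude=1.5, fold_wavelength=12.0,
        noise_sd=0.03, bias_amplitude=0.1, cluster_offset=(2.0, 0.0, 0.0),
        n_frames=120, stimulus_period=20.0, seed=7,
    )


@pytest.fixture
def noisy_phantom(noisy_spec):
    return make_phantom(noisy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def patch_center_vertex(surface, truth):
    """Vertex nearest the true patch centre."""
    d = np.linalg.norm(surface.midthickness - truth.patch_center_world, axis=1)
    return int(np.argmin(d))
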