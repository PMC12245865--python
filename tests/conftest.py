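import numpy as np
import pytest

from endosplat.scene import Camera, GaussianCloud
from endosplat.experiments import random_cloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_camera():
    """64x64 camera at the origin looking down +z."""
    return Camera(fx=60.0, fy=60.0, cx=32.0, cy=32.0, width=64, height=64,
                  znear=0.1)


@pytest.fixture
def small_cloud(rng):
    """50 random Gaussians in front of the origin camera."""
    return random_cloud(rng, 50)


@pytest.fixture
def single_splat_cloud():
    """One isotropic, well-resolved Gaussian on the optical axis."""
    return GaussianCloud(
        means=np.array([[0.0, 0.0, 2.0]]),
        rot_quats=np.array([[1.0, 0.0, 0.0, 0.0]]),
        log_scales=np.log(np.full((1, 3), 0.35)),
        opacity_logits=np.array([np.log(0.8 / 0.2)]),  # sigma = 0.8
        sh_coeffs=((np.array([[0.9, 0.4, 0.2]]) - 0.5)
                   / 0.28209479177387814)[:, None, :],
        sh_degree=0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic tube dataset shared across training tests."""
    from endosplat.synthetic import SceneSpec, generate_dataset
    spec = SceneSpec(seed=3, n_gaussians=300, width=96, height=54)
    return generate_dataset(spec, n_frames=12)
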