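import numpy as np
import pytest

from aggdeblur import BlurSpec, blur_image, generate_synthetic_scene
from aggdeblur.iqa.metrics import register_backend


@pytest.fixture()
def mock_learned_metrics():
    """Stand-in backends for DISTS/LPIPS: perfect-quality constants."""
    register_backend("DISTS", lambda r, t: 0.0)
    register_backend("LPIPS", lambda r, t: 0.0)
    yield
    register_backend("DISTS", None)
    register_backend("LPIPS", None)


@pytest.fixture(scope="session")
def scene64():
    return generate_synthetic_scene(64, 64, seed=0)


@pytest.fixture(scope="session")
def scene_batch():
    return [generate_synthetic_scene(64, 64, seed=i) for i in range(12)]


def make_blurred(scene, intensity, seed=0, n_steps=60, kernel_size=21):
    # trajectory sampling is kept coarse (n_steps=60) at fixture scale so the
    # per-step displacement stays resolvable and blur strength responds to
    # the intensity parameter (dense paths self-average into fixed blobs)
    return blur_image(scene, BlurSpec(intensity=intensity, n_steps=n_steps,
                                      kernel_size=kernel_size, seed=seed))


@pytest.fixture(scope="session")
def blurred_batch(scene_batch):
    return [make_blurred(s, 0.5, seed=100 + i) for i, s in enumerate(scene_batch)]
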