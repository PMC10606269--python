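import numpy as np
import pytest

from partprune import PhantomConfig, build_unet, generate_dataset, init_weights


@pytest.fixture(scope="session")
def toy_unet():
    """Depth-2 U-Net on 16x16 inputs, 3 classes."""
    return build_unet(depth=2, base_channels=4, in_shape=(16, 16), n_classes=3)


@pytest.fixture(scope="session")
def toy_weights(toy_unet):
    return init_weights(toy_unet, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 small phantoms, split 8/2/2."""
    cfg = PhantomConfig(n_samples=12, image_size=(32, 32), seed=5,
                        kidney_axes_range=((5, 7), (4, 5)),
                        tumor_radius_range=(2, 3))
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
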