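import numpy as np
import pytest

from unetbench import PhantomParams, VariantSpec, generate_dataset, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spec():
    """Smallest doubling spec: 1 encoder level, 2 initial filters, no BN."""
    return VariantSpec(name="toy", encoder_levels=1, width_mode="doubling",
                       initial_filters=2)


@pytest.fixture
def small_spec():
    """A 2-level fixed-width spec cheap enough for training tests."""
    return VariantSpec(name="small8", encoder_levels=2, width_mode="fixed",
                       fixed_filters=8)


@pytest.fixture
def tiny_phantom_params():
    """Noise-free 32x32 phantoms for fast pipeline tests."""
    return PhantomParams(size=(32, 32), noise_sigma=0.0, rib_amplitude=0.0,
                         background_level=0.85, lung_contrast=0.55, seed=11)


@pytest.fixture
def tiny_dataset(tmp_path, tiny_phantom_params):
    """12 phantom pairs on disk in the directory convention, plus manifest."""
    root = tmp_path / "ds"
    manifest = generate_dataset(12, tiny_phantom_params, root)
    return root, manifest
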