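import numpy as np
import pytest

from petlymph import Modality, PhantomConfig, Volume, generate_phantom
from petlymph.network import NetworkConfig, prepare_case


def tiny_network_config(**overrides):
    defaults = dict(
        n_pathways=2,
        downsample_factors=(1, 3),
        conv_features=(4, 4, 4, 4, 4, 4, 4, 4),
        fc_features=8,
        patch_size=19,
        epochs=2,
        batches_per_epoch=4,
        batch_size=4,
        seed=0,
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """One 48^3 phantom with default (noisy, blurred) imaging."""
    return generate_phantom(PhantomConfig(grid_size=48, seed=7))


@pytest.fixture(scope="session")
def small_prepared(small_phantom):
    case, _ = small_phantom
    return prepare_case(case)


def make_volume(data, spacing=(2.0, 2.0, 2.0), modality=Modality.PET_SUV):
    return Volume(data=np.asarray(data), spacing=spacing, modality=modality)
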