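import numpy as np
import pytest

from dsfnet.network import NetworkConfig
from dsfnet.synthetic import PhantomSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_phantom_spec(seed: int = 7) -> PhantomSpec:
    """A 32 x 32 phantom: same difficulty structure, desk-scale geometry."""
    return PhantomSpec(
        image_size=32,
        n_teeth=3,
        crown_radius_range=(3.5, 5.0),
        root_length_range=(5.0, 9.0),
        root_width_range=(1.2, 2.0),
        boundary_blur_sigma=0.7,
        noise_sd=40.0,
        streak_artifact_prob=0.3,
        seed=seed,
    )


def tiny_network_config(**kw) -> NetworkConfig:
    defaults = dict(base_channels=8, input_size=32, token_grid=4, heads=2)
    defaults.update(kw)
    return NetworkConfig(**defaults)


@pytest.fixture(scope="session")
def phantom_dataset_dir(tmp_path_factory):
    """Five tiny phantom volumes on disk, shared across tests."""
    out = tmp_path_factory.mktemp("phantoms")
    generate_dataset(tiny_phantom_spec(), n_volumes=5, slices_per_volume=10,
                     out_dir=out)
    return out
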