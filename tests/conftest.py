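import numpy as np
import pytest

from voxelstab.design import starplus_design
from voxelstab.synthetic import SyntheticSpec, make_starplus_like


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """80-sample binary dataset, 5 informative of 100 voxels at 4 sigma."""
    spec = SyntheticSpec(
        design=starplus_design(),
        grid_dims=(8, 8, 4),
        n_voxels=100,
        n_informative=5,
        cluster_radius=0.0,
        effect_size=4.0,
        noise_sd=1.0,
        seed=42,
    )
    return make_starplus_like(spec)


@pytest.fixture()
def split_80():
    """Deterministic 60/10/10 train/val/test index split of 80 samples."""
    rng = np.random.default_rng(7)
    perm = rng.permutation(80)
    return perm[:60], perm[60:70], perm[70:]
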