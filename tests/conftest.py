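import numpy as np
import pytest

from rehopipe.io import BoldSeries, BrainMask
from rehopipe.synth import RoiSpec, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small cohort that runs every stage in a couple of seconds."""
    return SyntheticConfig(
        shape=(12, 12, 12), n_timepoints=60, n_per_group=4,
        rois=(RoiSpec("sfg", (4, 4, 7), 2, 0.1, 0.6),),
        seed=99,
    )


@pytest.fixture
def box_bold(rng):
    """8x8x8 i.i.d. noise volume with a full box mask, 40 frames."""
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    data = rng.standard_normal((8, 8, 8, 40))
    bold = BoldSeries(data=data, affine=affine, tr_seconds=2.0, subject_id="toy")
    mask = BrainMask(data=np.ones((8, 8, 8), dtype=bool), affine=affine)
    return bold, mask
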