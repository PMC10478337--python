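import numpy as np
import pytest

from atstseg.io import HUVolume, LabelMask
from atstseg.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One deterministic mid-size phantom with all ground-truth masks."""
    spec = PhantomSpec(shape=(64, 64, 8), seed=42)
    vol, lung, lesion, subtypes = generate_phantom(spec)
    return {"spec": spec, "volume": vol, "lung": lung, "lesion": lesion,
            "subtypes": subtypes}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_volume():
    """4x4x2 volume with hand-picked HU values for exhaustive checks."""
    vox = np.full((4, 4, 2), 40.0, dtype=np.float32)
    vox[0, 0, 0] = -500.0   # GGO-range
    vox[1, 1, 0] = -100.0   # consolidation-range
    vox[2, 2, 0] = -800.0   # below lesion band
    vox[3, 3, 0] = -300.0   # boundary: consolidation
    vox[0, 1, 1] = -750.0   # boundary: GGO
    return HUVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))


def random_mask(rng, shape=(12, 12), p=0.3):
    return LabelMask((rng.random(shape) < p).astype(np.uint8))
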