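import numpy as np
import pytest

from chdseg.phantom import PhantomConfig, generate_study
from chdseg.preprocess import PreprocessConfig, build_pairs


@pytest.fixture(scope="session")
def default_study():
    """13-slice phantom at full source resolution, default geometry."""
    return generate_study(PhantomConfig(seed=5))


@pytest.fixture(scope="session")
def small_study():
    """Compact phantom (4 slices, no empty apex) for fast pipeline tests."""
    return generate_study(PhantomConfig(n_slices=4, apical_empty_slice=False,
                                        seed=11))


@pytest.fixture(scope="session")
def pairs32(small_study):
    """Preprocessed pairs at 32x32 (all chambers/phases)."""
    return build_pairs(small_study, PreprocessConfig(target_size=32))


@pytest.fixture(scope="session")
def lv_pairs32(pairs32):
    return [p for p in pairs32 if p.chamber == "LV"]


def random_mask(rng, shape=(8, 8), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)
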