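import numpy as np
import pytest

from isletscope.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless phantom with well-separated islets, shared across
    tests (generation is deterministic, so sharing is safe)."""
    spec = PhantomSpec(shape=(64, 128, 128), n_islets=8, seed=1)
    insulin, ki67, cd45, truth = generate_phantom(spec)
    return spec, insulin, ki67, cd45, truth


@pytest.fixture()
def fixed_level():
    """Threshold halfway between background and islet intensity for the
    default phantom rendering."""
    return (20000.0 + 100.0) / 2.0


def segment_exact(volume, level=(20000.0 + 100.0) / 2.0):
    from isletscope.segmentation import threshold_segment

    return threshold_segment(volume, method="fixed", level=level)
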