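import numpy as np
import pytest

from sctdoseval.grids import BinaryMask, ScalarVolume, VolumeGrid


def grid(size=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VolumeGrid(origin=origin, spacing=spacing, size=size)


def uniform(value, g=None):
    g = g or grid()
    return ScalarVolume(g, np.full(g.size, value, dtype=np.float32))


def full_mask(g=None):
    g = g or grid()
    return BinaryMask(g, np.ones(g.size, dtype=bool))


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom shared across tests (deterministic)."""
    from sctdoseval.synthetic import make_phantom

    return make_phantom(seed=11)


@pytest.fixture(scope="session")
def corrupted_sct(default_phantom):
    from sctdoseval.synthetic import CorruptionSpec, corrupt_to_sct

    return corrupt_to_sct(
        default_phantom.ct, default_phantom.geometry, CorruptionSpec(seed=12)
    )
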