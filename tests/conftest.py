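import numpy as np
import pytest

import usblt as u


@pytest.fixture(scope="session")
def tiny_mesh():
    """75-node slab for brute-force oracles."""
    return u.build_slab_mesh((8.0, 8.0, 4.0), 2.0)


@pytest.fixture(scope="session")
def unit_cube():
    return u.build_slab_mesh((1.0, 1.0, 1.0), 1.0)


@pytest.fixture(scope="session")
def slab_4851():
    """The desk-scale slab geometry: 40 x 40 x 20 mm at 2 mm spacing."""
    return u.build_slab_mesh((40.0, 40.0, 20.0), 2.0)


@pytest.fixture(scope="session")
def small_testbed():
    """Small end-to-end testbed: 20 x 20 x 12 mm slab, 25 detectors."""
    cfg = u.ExperimentConfig(
        dimensions=(20.0, 20.0, 12.0),
        spacing=2.0,
        detector_extent=(12.0, 12.0),
        detector_pitch=3.0,
        sources=(u.SourceSpec(center=(0.0, 0.0, 5.0)),),
        realizations=5,
    )
    return u.Testbed(cfg)


@pytest.fixture(scope="session")
def testbed():
    """The full desk-scale study testbed (the slab protocol at 2 mm nodes
    and a 3 mm detector pitch)."""
    return u.Testbed(u.ExperimentConfig())
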