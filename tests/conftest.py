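import numpy as np
import pytest

from agpfret import synthetic_data as sd
from agpfret.structure_io import default_scheme


@pytest.fixture(scope="session")
def agp1_dimer():
    return sd.make_toy_dimer("agp1")


@pytest.fixture(scope="session")
def agp2_dimer():
    return sd.make_toy_dimer("agp2")


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def true_complex(agp1_dimer, agp2_dimer):
    """The reference true-pose complex (no decoys)."""
    ensemble = sd.make_pose_ensemble(agp2_dimer, agp1_dimer, n_decoys=0, seed=7)
    return ensemble[0]


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a bounded translation."""
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-100, 100, 3)
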