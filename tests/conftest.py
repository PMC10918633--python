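import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapeflex import Molecule3D, RigidTransform, RunConfig
from shapeflex.fixtures import BUNDLED_SMILES, embed_smiles

_SMILES = dict(BUNDLED_SMILES)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def molecule_factory():
    """Deterministic 3D structures from the bundled SMILES list (cached)."""
    cache = {}

    def build(name, seed=1, smiles=None):
        key = (name, seed)
        if key not in cache:
            cache[key] = embed_smiles(smiles or _SMILES[name], name=name, seed=seed)
        return cache[key]

    return build


@pytest.fixture
def methane():
    # explicit construction: tetrahedral CH4, C at origin
    d = 1.09 / np.sqrt(3.0)
    coords = np.array(
        [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]], dtype=float
    )
    return Molecule3D(
        ["C", "H", "H", "H", "H"],
        [0] * 5,
        coords,
        [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
        name="methane",
    )


@pytest.fixture
def water():
    coords = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
    return Molecule3D(["O", "H", "H"], [0, 0, 0], coords, [(0, 1, 1), (0, 2, 1)], name="water")


def random_rigid_transform(rng, angle_deg=None, translation=None):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(0, 180) if angle_deg is None else angle_deg
    R = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
    t = rng.normal(size=3)
    if translation is not None:
        t = translation * t / np.linalg.norm(t)
    return RigidTransform.from_rotation_translation(R, t)
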