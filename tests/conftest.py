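"""Shared test fixtures: synthetic molecules and on-disk structure files."""

import numpy as np
import pytest

from hypershape import FixtureSpec, Molecule, generate, write_fixture_files


@pytest.fixture
def random_cloud() -> Molecule:
    return generate(FixtureSpec("random_cloud", seed=11, n_atoms=9))


@pytest.fixture
def chiral_tetrahedron() -> Molecule:
    return generate(FixtureSpec("chiral_tetrahedron", seed=1))


@pytest.fixture
def planar_cloud() -> Molecule:
    return generate(FixtureSpec("planar", seed=3, n_atoms=7))


@pytest.fixture
def linear_symmetric() -> Molecule:
    return generate(FixtureSpec("linear_symmetric", seed=0))


def reflect(molecule: Molecule, axis: int = 0, suffix: str = "_mirror") -> Molecule:
    """Exact reflection of a molecule through the plane normal to ``axis``."""
    coords = molecule.coordinates.copy()
    coords[:, axis] = -coords[:, axis]
    return molecule.with_coordinates(coords, name=molecule.name + suffix)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.normal(scale=5.0, size=3)
    return rotation, translation


@pytest.fixture
def fixture_files(tmp_path):
    """A directory of SDF files written through the real I/O path."""
    paths = write_fixture_files(
        FixtureSpec("mirror_pair", seed=4, n_atoms=8), tmp_path, format="sdf"
    )
    return paths
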