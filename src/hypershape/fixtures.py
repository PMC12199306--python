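"""Deterministic synthetic molecular fixtures.

Every generator is a pure function of (spec, seed): same spec + seed gives
bit-identical output.  The fixture kinds exercise each behaviour of the
similarity pipeline:

* ``random_cloud`` — a generic asymmetric point cloud of mixed elements.
* ``chiral_tetrahedron`` — four distinct atoms with a nonzero triple
  product, the minimal chiral shape.
* ``mirror_pair`` — a cloud and its exact x -> -x reflection.
* ``torsion_sweep`` — conformers along a single-dihedral path constructed
  so a USR reference atom (ftf, the atom farthest from the atom farthest
  from the centroid) switches identity mid-sweep: one distal atom rotates
  about an axle while a rival distal atom sits at a fixed distance, and
  the sweep window is centred (numerically, by bisection) on the distance
  crossing.  Atom-anchored methods jump there; PC-anchored ones do not.
* ``isotopologue_series`` — amine-like heavy-atom chains of growing
  length, paired with a single 13C-labelled copy.
* ``protonation_series`` — base/protonated chain pairs differing by one
  added H and a +1 formal charge on the nitrogen.
* ``linear_symmetric`` — an acetylene-like collinear molecule with a
  mirror plane orthogonal to its first PC (undetermined-axis case).
* ``planar`` — an achiral, strictly planar cloud (chirality control).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .errors import FixtureSpecError
from .io import AtomRecord, Molecule, write_molecule

__all__ = ["FixtureSpec", "generate", "write_fixture_files", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "random_cloud",
    "chiral_tetrahedron",
    "mirror_pair",
    "torsion_sweep",
    "isotopologue_series",
    "protonation_series",
    "linear_symmetric",
    "planar",
)

_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    n_atoms: int = 10
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise FixtureSpecError(f"unknown fixture kind {self.kind!r}")
        if self.n_atoms < 1:
            raise FixtureSpecError("n_atoms must be >= 1")


def _mol(symbols, coords, name, charges=None, isotopes=None) -> Molecule:
    atoms = []
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    for i, (sym, xyz) in enumerate(zip(symbols, coords)):
        atoms.append(
            AtomRecord(
                element_symbol=sym,
                atomic_number=pt.GetAtomicNumber(sym),
                coords=np.asarray(xyz, float),
                formal_charge=0 if charges is None else int(charges[i]),
                mass_number=None if isotopes is None else isotopes[i],
            )
        )
    return Molecule(atoms, name=name)


def _random_cloud(spec: FixtureSpec) -> Molecule:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    coords = rng.normal(scale=spec.parameters.get("spread", 2.0), size=(n, 3))
    symbols = rng.choice(_ELEMENTS, size=n)
    return Molecule(
        _mol(symbols, coords, f"random_cloud_{spec.seed}").atoms,
        name=f"random_cloud_{spec.seed}",
    )


def _chiral_tetrahedron(spec: FixtureSpec) -> Molecule:
    rng = np.random.default_rng(spec.seed)
    base = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.6, 0.0, 0.0],
            [0.3, 1.4, 0.1],
            [0.2, 0.4, 1.3],
        ]
    )
    coords = base + rng.normal(scale=0.05, size=base.shape)
    # retry jitter (derived sub-seeds) until the tetrahedron is robustly chiral
    for attempt in range(100):
        v1, v2, v3 = coords[1] - coords[0], coords[2] - coords[0], coords[3] - coords[0]
        if abs(np.dot(v1, np.cross(v2, v3))) > 0.1:
            break
        sub = np.random.default_rng((spec.seed + 1) * 1000 + attempt)
        coords = base + sub.normal(scale=0.05, size=base.shape)
    return _mol(["H", "C", "N", "O"], coords, f"chiral_tetrahedron_{spec.seed}")


def _mirror_pair(spec: FixtureSpec) -> list[Molecule]:
    base_kind = spec.parameters.get("base_kind", "random_cloud")
    base_spec = FixtureSpec(base_kind, seed=spec.seed, n_atoms=spec.n_atoms)
    original = generate(base_spec)
    if isinstance(original, list):
        raise FixtureSpecError("mirror_pair base kind must yield a single molecule")
    mirrored_coords = original.coordinates.copy()
    mirrored_coords[:, 0] = -mirrored_coords[:, 0]
    mirrored = original.with_coordinates(mirrored_coords, name=original.name + "_mirror")
    return [original, mirrored]


def _torsion_sweep(spec: FixtureSpec) -> list[Molecule]:
    rng = np.random.default_rng(spec.seed)
    n_steps = int(spec.parameters.get("n_steps", 21))
    half_window = float(spec.parameters.get("half_window", 0.10))
    if n_steps < 3:
        raise FixtureSpecError("torsion_sweep needs at least 3 steps")

    # fixed skeleton: far cap A (becomes ftc), rival distal atom B (out of
    # the rotor plane, so the two ftf candidates are well separated at the
    # switch), rotor C about an axle, and bulk atoms with dedicated y- and
    # z-anisotropy anchors so the PC frame stays stable across the sweep.
    a_pos = np.array([5.0, 0.0, 0.0])
    b_pos = np.array([-4.0, 0.3, 1.2]) + rng.normal(scale=0.03, size=3)
    axle_c = np.array([-3.0, 0.0, 0.0])
    radius = 1.8
    bulk = np.array(
        [
            [-0.4, 0.2, 0.1],   # ctc anchor near the centroid
            [0.0, 3.2, 0.3],    # y anchor
            [0.3, -0.6, -2.0],  # z anchor
            [-0.5, -1.0, 0.5],
            [0.5, 0.7, 0.8],
        ]
    ) + rng.normal(scale=0.05, size=(5, 3))

    def rotor(theta: float) -> np.ndarray:
        return axle_c + radius * np.array([np.cos(theta), np.sin(theta), 0.0])

    # locate the |rotor - A| vs |B - A| distance crossing by bisection so the
    # ftf reference atom switches inside the sweep window by construction
    d_rival = np.linalg.norm(b_pos - a_pos)

    def gap(theta: float) -> float:
        return float(np.linalg.norm(rotor(theta) - a_pos) - d_rival)

    lo, hi = 1.6, 3.1  # gap < 0 at lo, > 0 at hi for this skeleton
    if gap(lo) >= 0 or gap(hi) <= 0:
        raise FixtureSpecError("torsion sweep skeleton lost its reference-atom crossing")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    theta_star = 0.5 * (lo + hi)

    thetas = np.linspace(theta_star - half_window, theta_star + half_window, n_steps)
    symbols = ["C", "N", "O", "C", "C", "S", "P", "F"]
    conformers = []
    for step, theta in enumerate(thetas):
        coords = np.vstack([a_pos, b_pos, rotor(theta), bulk])
        conformers.append(_mol(symbols, coords, f"torsion_{spec.seed}_{step:03d}"))
    return conformers


def _chain_coords(n_heavy: int) -> np.ndarray:
    """Zigzag heavy-atom chain, 1.5 A bonds, ~111 deg angles, in the xz-plane."""
    bond, half_angle = 1.5, np.deg2rad(111.0) / 2.0
    dx, dz = bond * np.sin(half_angle), bond * np.cos(half_angle)
    coords = np.zeros((n_heavy, 3))
    for i in range(1, n_heavy):
        coords[i, 0] = coords[i - 1, 0] + dx
        coords[i, 2] = dz if i % 2 else 0.0
    return coords


def _amine_chain(n_carbons: int, name: str) -> Molecule:
    coords = _chain_coords(n_carbons + 1)
    symbols = ["N"] + ["C"] * n_carbons
    return _mol(symbols, coords, name)


def _isotopologue_series(spec: FixtureSpec) -> list[tuple[Molecule, Molecule]]:
    lengths = spec.parameters.get("lengths", (3, 5, 7, 9))
    pairs = []
    for n_carbons in lengths:
        if n_carbons < 1:
            raise FixtureSpecError("chain length must be >= 1")
        base = _amine_chain(n_carbons, f"amine_C{n_carbons}")
        labeled = _amine_chain(n_carbons, f"amine_C{n_carbons}_13C")
        labeled.atoms[1].mass_number = 13  # label the carbon bonded to N
        pairs.append((base, labeled))
    return pairs


def _protonation_series(spec: FixtureSpec) -> list[tuple[Molecule, Molecule]]:
    lengths = spec.parameters.get("lengths", (3, 5, 7))
    pairs = []
    for n_carbons in lengths:
        base = _amine_chain(n_carbons, f"amine_C{n_carbons}")
        proton = AtomRecord("H", 1, np.array([-0.55, 0.75, -0.45]))
        atoms = [
            AtomRecord(
                a.element_symbol,
                a.atomic_number,
                a.coords.copy(),
                a.mass_number,
                1 if i == 0 else 0,  # +1 on the nitrogen
            )
            for i, a in enumerate(base.atoms)
        ]
        protonated = Molecule(atoms + [proton], name=f"amine_C{n_carbons}_H+")
        pairs.append((base, protonated))
    return pairs


def _linear_symmetric(spec: FixtureSpec) -> Molecule:
    # acetylene-like: H-C...C-H collinear with an exact mirror plane
    coords = np.array(
        [
            [-1.665, 0.0, 0.0],
            [-0.6, 0.0, 0.0],
            [0.6, 0.0, 0.0],
            [1.665, 0.0, 0.0],
        ]
    )
    return _mol(["H", "C", "C", "H"], coords, f"linear_symmetric_{spec.seed}")


def _planar(spec: FixtureSpec) -> Molecule:
    rng = np.random.default_rng(spec.seed)
    n = max(spec.n_atoms, 5)
    coords = np.zeros((n, 3))
    coords[:, :2] = rng.normal(scale=1.8, size=(n, 2))
    symbols = rng.choice(_ELEMENTS, size=n)
    return _mol(symbols, coords, f"planar_{spec.seed}")


_GENERATORS = {
    "random_cloud": _random_cloud,
    "chiral_tetrahedron": _chiral_tetrahedron,
    "mirror_pair": _mirror_pair,
    "torsion_sweep": _torsion_sweep,
    "isotopologue_series": _isotopologue_series,
    "protonation_series": _protonation_series,
    "linear_symmetric": _linear_symmetric,
    "planar": _planar,
}


def generate(spec: FixtureSpec):
    """Generate the fixture named by ``spec``.

    Returns a single :class:`Molecule` (random_cloud, chiral_tetrahedron,
    linear_symmetric, planar), a list of molecules (mirror_pair,
    torsion_sweep) or a list of molecule pairs (isotopologue_series,
    protonation_series).
    """
    return _GENERATORS[spec.kind](spec)


def write_fixture_files(spec: FixtureSpec, out_dir: str | Path, format: str = "sdf") -> list[Path]:
    """Generate a fixture and write each molecule as an SDF or XYZ file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = generate(spec)
    molecules: list[Molecule] = []
    if isinstance(result, Molecule):
        molecules = [result]
    else:
        for item in result:
            molecules.extend(item if isinstance(item, tuple) else [item])
    paths = []
    for mol in molecules:
        path = out_dir / f"{mol.name}.{format.lower()}"
        write_molecule(mol, path, format=format)
        paths.append(path)
    return paths
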