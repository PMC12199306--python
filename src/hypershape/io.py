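"""Reading and writing molecular structures and per-atom feature tables.

Structures are exposed as a format-neutral :class:`Molecule` record: an
ordered list of atoms, each carrying its element, mass number (isotope),
formal charge, Cartesian coordinates in Angstrom, and any user-supplied
numerical features.  Atom order is preserved exactly as read; hydrogens are
used exactly as present in the input — nothing is added, removed or
sanitized, because downstream fingerprints operate on the supplied point
cloud and silent atom edits would change them unpredictably.

Parsing of SDF/MOL (V2000), PDB and XYZ goes through RDKit with
sanitization disabled.  V3000 connection tables are rejected explicitly:
the package guarantees bit-exact behaviour only for the V2000 dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import (
    ElementError,
    EmptyMoleculeError,
    FeatureTableError,
    MoleculeParseError,
)

__all__ = [
    "AtomRecord",
    "Molecule",
    "read_molecule",
    "write_molecule",
    "read_feature_table",
    "most_common_mass_number",
]

_PT = Chem.GetPeriodicTable()

#: element symbol used for property-annotated dummy atoms
DUMMY_SYMBOL = "*"


def most_common_mass_number(atomic_number: int) -> int:
    """Mass number of the highest-natural-abundance isotope of an element.

    Backed by RDKit's periodic table; raises :class:`ElementError` for
    atomic numbers it does not cover.
    """
    if atomic_number < 1:
        raise ElementError(f"no isotope table entry for atomic number {atomic_number}")
    mass = _PT.GetMostCommonIsotope(atomic_number)
    if mass <= 0:
        raise ElementError(f"no most-common isotope known for Z={atomic_number}")
    return int(mass)


@dataclass
class AtomRecord:
    """One atom of a molecule.

    ``mass_number`` is ``None`` when the input file did not specify an
    isotope; the most common isotope is then assumed wherever a neutron
    count is needed.  ``extra_features`` holds user-supplied per-atom
    numbers (e.g. partial charges) keyed by dimension name, in insertion
    order.
    """

    element_symbol: str
    atomic_number: int
    coords: np.ndarray
    mass_number: int | None = None
    formal_charge: int = 0
    extra_features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        is_dummy = self.element_symbol == DUMMY_SYMBOL
        if self.atomic_number < 1 and not is_dummy:
            raise ElementError(
                f"atomic number must be >= 1 (got {self.atomic_number} "
                f"for {self.element_symbol!r})"
            )
        if self.mass_number is not None and self.mass_number < self.atomic_number:
            raise ValueError(
                f"mass number {self.mass_number} < atomic number {self.atomic_number}"
            )

    @property
    def neutron_count(self) -> int:
        """n = mass number - proton count (most common isotope if unset)."""
        mass = (
            self.mass_number
            if self.mass_number is not None
            else most_common_mass_number(self.atomic_number)
        )
        return mass - self.atomic_number


@dataclass
class Molecule:
    """An ordered collection of atoms read from one structure."""

    atoms: list[AtomRecord]
    name: str = ""
    source_format: str = "RAW"

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise EmptyMoleculeError(f"molecule {self.name!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(A, 3) array of Cartesian coordinates in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray, name: str | None = None) -> "Molecule":
        """Copy of the molecule with replaced coordinates (same atoms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(
                element_symbol=a.element_symbol,
                atomic_number=a.atomic_number,
                coords=coords[i],
                mass_number=a.mass_number,
                formal_charge=a.formal_charge,
                extra_features=dict(a.extra_features),
            )
            for i, a in enumerate(self.atoms)
        ]
        return Molecule(atoms, name=self.name if name is None else name,
                        source_format=self.source_format)


def _molecule_from_rdkit(mol: Chem.Mol, name: str, source_format: str) -> Molecule:
    if mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError(f"{name!r}: zero atoms")
    if mol.GetNumConformers() == 0:
        raise MoleculeParseError(f"{name!r}: no 3D coordinates present")
    conf = mol.GetConformer()
    atoms: list[AtomRecord] = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        iso = atom.GetIsotope()
        atoms.append(
            AtomRecord(
                element_symbol=atom.GetSymbol(),
                atomic_number=atom.GetAtomicNum(),
                coords=np.array([pos.x, pos.y, pos.z]),
                mass_number=int(iso) if iso else None,
                formal_charge=atom.GetFormalCharge(),
            )
        )
    return Molecule(atoms, name=name, source_format=source_format)


def _read_sdf(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if len(lines) > 3 and "V3000" in lines[3]:
        raise MoleculeParseError(f"{path}: V3000 connection tables are not supported")
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    try:
        mol = next(iter(supplier))
    except StopIteration:  # pragma: no cover - empty file
        mol = None
    if mol is None:
        raise MoleculeParseError(f"{path}: unparseable SDF/MOL block")
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return _molecule_from_rdkit(mol, name or path.stem, "SDF")


def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise MoleculeParseError(f"{path}: truncated XYZ file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise MoleculeParseError(f"{path}: line 1 is not an atom count") from exc
    if n_atoms == 0:
        raise EmptyMoleculeError(f"{path}: zero atoms")
    if len(lines) < 2 + n_atoms:
        raise MoleculeParseError(
            f"{path}: expected {n_atoms} atom lines, found {len(lines) - 2}"
        )
    atoms: list[AtomRecord] = []
    for i, line in enumerate(lines[2 : 2 + n_atoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise MoleculeParseError(f"{path}: malformed atom record at line {i}")
        symbol = parts[0]
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise MoleculeParseError(
                f"{path}: non-numeric coordinate at line {i}"
            ) from exc
        if symbol == DUMMY_SYMBOL:
            z = 0
        else:
            try:
                z = _PT.GetAtomicNumber(symbol)
            except Exception as exc:
                raise ElementError(f"{path}: unknown element {symbol!r} at line {i}") from exc
            if z == 0:
                raise ElementError(f"{path}: unknown element {symbol!r} at line {i}")
        atoms.append(AtomRecord(symbol, z, np.array(xyz)))
    return Molecule(atoms, name=lines[1].strip() or path.stem, source_format="XYZ")


def _read_pdb(path: Path) -> Molecule:
    mol = Chem.MolFromPDBFile(
        str(path), sanitize=False, removeHs=False, proximityBonding=False
    )
    if mol is None:
        raise MoleculeParseError(f"{path}: unparseable PDB file")
    return _molecule_from_rdkit(mol, path.stem, "PDB")


_READERS = {"SDF": _read_sdf, "MOL": _read_sdf, "XYZ": _read_xyz, "PDB": _read_pdb}
_SUFFIXES = {".sdf": "SDF", ".mol": "SDF", ".xyz": "XYZ", ".pdb": "PDB"}


def read_molecule(path: str | Path, format: str | None = None) -> Molecule:
    """Read one molecule from an SDF/MOL (V2000), XYZ or PDB file.

    Coordinates are taken as Angstrom.  Isotopes absent from the file leave
    ``mass_number`` unset (most common isotope assumed downstream); absent
    formal charges default to 0.  No hydrogens are added or removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _SUFFIXES.get(path.suffix.lower(), "")).upper()
    if fmt not in _READERS:
        raise MoleculeParseError(
            f"{path}: unknown format {fmt!r} (expected SDF, XYZ or PDB)"
        )
    return _READERS[fmt](path)


def _to_rdkit(molecule: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(molecule))
    for i, a in enumerate(molecule.atoms):
        atom = Chem.Atom(a.atomic_number)
        atom.SetFormalCharge(a.formal_charge)
        atom.SetNoImplicit(True)
        if a.mass_number is not None:
            atom.SetIsotope(a.mass_number)
        rw.AddAtom(atom)
        conf.SetAtomPosition(i, [float(v) for v in a.coords])
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", molecule.name)
    return mol


def write_molecule(molecule: Molecule, path: str | Path, format: str | None = None) -> None:
    """Write a molecule to SDF (V2000) or XYZ.

    SDF output records formal charges (M  CHG) and explicit isotopes
    (M  ISO); coordinates are written at the standard 4-decimal V2000
    precision.
    """
    path = Path(path)
    fmt = (format or _SUFFIXES.get(path.suffix.lower(), "")).upper()
    if fmt in ("SDF", "MOL"):
        block = Chem.MolToMolBlock(_to_rdkit(molecule), kekulize=False)
        path.write_text(block + "$$$$\n")
    elif fmt == "XYZ":
        lines = [str(len(molecule)), molecule.name]
        for a in molecule.atoms:
            x, y, z = a.coords
            lines.append(f"{a.element_symbol} {x:.6f} {y:.6f} {z:.6f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise MoleculeParseError(f"{path}: cannot write format {fmt!r}")


def read_feature_table(path: str | Path, molecule: Molecule) -> dict[int, dict[str, float]]:
    """Attach a CSV of per-atom features (header row = dimension names).

    Row ``i`` of the table maps onto atom ``i`` of the molecule; the row
    count must equal the atom count.  Features are also written into each
    atom's ``extra_features`` so named schemes can reference them.
    """
    table = pd.read_csv(path)
    if len(table) != len(molecule):
        raise FeatureTableError(
            f"{path}: table has {len(table)} rows but molecule "
            f"{molecule.name!r} has {len(molecule)} atoms"
        )
    result: dict[int, dict[str, float]] = {}
    for i, row in enumerate(table.itertuples(index=False)):
        feats: dict[str, float] = {}
        for col, value in zip(table.columns, row):
            if isinstance(value, str) or (
                not isinstance(value, (int, float, np.integer, np.floating))
            ):
                raise FeatureTableError(
                    f"{path}: non-numeric cell at row {i}, column {col!r}"
                )
            value = float(value)
            if not math.isfinite(value):
                raise FeatureTableError(
                    f"{path}: non-finite cell at row {i}, column {col!r}"
                )
            feats[str(col)] = value
        molecule.atoms[i].extra_features.update(feats)
        result[i] = feats
    return result
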