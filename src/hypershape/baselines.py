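"""Heuristic-reference baseline methods: USR, CSR, USR:OptIso, subset fingerprints.

USR (Ultrafast Shape Recognition) anchors four reference points on the
molecule itself: the centroid (ctd), the atom closest to the centroid
(ctc), the atom farthest from the centroid (ftc) and the atom farthest
from ftc (ftf).  The first three moments of the four distance
distributions give a 12-number, chirality-blind fingerprint.

CSR replaces the ctc distribution with one anchored at
ctd + (ctd->ftc) x (ctd->ftf); the cross product is not invariant under
reflection, making the 12-number fingerprint enantiosensitive.
USR:OptIso instead keeps the USR fingerprint and appends the scalar triple
product (ctd->ctc) . ((ctd->ftc) x (ctd->ftf)) as a 13th component.

Subset fingerprints follow the USRCAT layout — a 12-moment block for all
atoms followed by one block per atom-type subset (60 numbers for the four
classic pharmacophoric types) — with the subset predicates fully
pluggable.  The bundled default predicates are deliberately simple
element-based rules (NOT the Credo SMARTS types): connectivity-dependent
typing is exactly what breaks down for molecules outside standard valence
rules.  Both the original atom-anchored engine and the PCA-frame engine
can produce the blocks, the latter reproducing the framework's emulation
of USR/USRCAT.

All heuristic atom selections break ties deterministically by lowest atom
index; a detected tie is recorded in the fingerprint notes because
tie-dependent reference points are a known source of input-order-dependent
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .fingerprint import Fingerprint, moment_triplet, molecule_fingerprint
from .io import AtomRecord, Molecule

__all__ = [
    "UsrReferencePoints",
    "AtomTypePredicate",
    "DEFAULT_PREDICATES",
    "usr_reference_points",
    "usr_fingerprint",
    "csr_reference",
    "csr_fingerprint",
    "optiso_descriptor",
    "optiso_fingerprint",
    "subset_fingerprint",
    "electroshape_fingerprint",
    "enrichment_factor",
]

_TIE_TOL = 1e-9
_CROSS_TOL = 1e-8


@dataclass(frozen=True)
class UsrReferencePoints:
    ctd: np.ndarray
    ctc: np.ndarray
    ftc: np.ndarray
    ftf: np.ndarray
    ctc_index: int
    ftc_index: int
    ftf_index: int
    had_tie: bool


def _argmin_with_tie(values: np.ndarray) -> tuple[int, bool]:
    idx = int(np.argmin(values))
    tie = bool(np.sum(np.abs(values - values[idx]) <= _TIE_TOL) > 1)
    return idx, tie


def _argmax_with_tie(values: np.ndarray) -> tuple[int, bool]:
    idx = int(np.argmax(values))
    tie = bool(np.sum(np.abs(values - values[idx]) <= _TIE_TOL) > 1)
    return idx, tie


def usr_reference_points(coords: np.ndarray) -> UsrReferencePoints:
    """ctd/ctc/ftc/ftf for a coordinate array, lowest-index tie-breaks."""
    coords = np.asarray(coords, dtype=float)
    ctd = coords.mean(axis=0)
    d_ctd = np.linalg.norm(coords - ctd, axis=1)
    i_ctc, tie1 = _argmin_with_tie(d_ctd)
    i_ftc, tie2 = _argmax_with_tie(d_ctd)
    d_ftc = np.linalg.norm(coords - coords[i_ftc], axis=1)
    i_ftf, tie3 = _argmax_with_tie(d_ftc)
    return UsrReferencePoints(
        ctd=ctd,
        ctc=coords[i_ctc],
        ftc=coords[i_ftc],
        ftf=coords[i_ftf],
        ctc_index=i_ctc,
        ftc_index=i_ftc,
        ftf_index=i_ftf,
        had_tie=tie1 or tie2 or tie3,
    )


def _moments_from_points(
    coords: np.ndarray, points: Sequence[np.ndarray], convention: str
) -> np.ndarray:
    dists = cdist(np.asarray(points, float), coords)
    return np.concatenate([moment_triplet(row, convention).as_tuple() for row in dists])


def usr_fingerprint(
    molecule: Molecule, skewness_convention: str = "standardized", method_tag: str = "USR"
) -> Fingerprint:
    """12-number USR fingerprint (moments of d_ctd, d_ctc, d_ftc, d_ftf)."""
    coords = molecule.coordinates
    refs = usr_reference_points(coords)
    values = _moments_from_points(
        coords, [refs.ctd, refs.ctc, refs.ftc, refs.ftf], skewness_convention
    )
    notes = ("reference-atom selection tie",) if refs.had_tie else ()
    return Fingerprint(
        values=values,
        n_dims=3,
        scheme_name="3d",
        method_tag=method_tag,
        name=molecule.name,
        notes=notes,
    )


def csr_reference(molecule: Molecule) -> np.ndarray:
    """Cross-product reference point: ctd + (ctd->ftc) x (ctd->ftf).

    Falls back to the USR ctc point (with a warning) when the cross
    product is degenerate (collinear ctd/ftc/ftf).
    """
    coords = molecule.coordinates
    refs = usr_reference_points(coords)
    cross = np.cross(refs.ftc - refs.ctd, refs.ftf - refs.ctd)
    if np.linalg.norm(cross) < _CROSS_TOL:
        warnings.warn(
            f"degenerate cross product for {molecule.name!r}; "
            "falling back to the USR ctc reference point",
            stacklevel=2,
        )
        return refs.ctc
    return refs.ctd + cross


def csr_fingerprint(molecule: Molecule, skewness_convention: str = "standardized") -> Fingerprint:
    """Chirality-sensitive 12-number fingerprint (ctc slot -> cross point)."""
    coords = molecule.coordinates
    refs = usr_reference_points(coords)
    cross_point = csr_reference(molecule)
    values = _moments_from_points(
        coords, [refs.ctd, cross_point, refs.ftc, refs.ftf], skewness_convention
    )
    notes = ("reference-atom selection tie",) if refs.had_tie else ()
    return Fingerprint(
        values=values,
        n_dims=3,
        scheme_name="3d",
        method_tag="CSR",
        name=molecule.name,
        notes=notes,
    )


def optiso_descriptor(molecule: Molecule) -> float:
    """Scalar triple product (ctd->ctc) . ((ctd->ftc) x (ctd->ftf)).

    Changes sign under reflection, vanishes for planar molecules.
    """
    refs = usr_reference_points(molecule.coordinates)
    return float(
        np.dot(refs.ctc - refs.ctd, np.cross(refs.ftc - refs.ctd, refs.ftf - refs.ctd))
    )


def optiso_fingerprint(molecule: Molecule, skewness_convention: str = "standardized") -> Fingerprint:
    """USR fingerprint plus the triple-product 13th component (K = 13)."""
    base = usr_fingerprint(molecule, skewness_convention)
    values = np.append(base.values, optiso_descriptor(molecule))
    return Fingerprint(
        values=values,
        n_dims=3,
        scheme_name="3d",
        method_tag="OPTISO",
        name=molecule.name,
        notes=base.notes,
    )


# ---------------------------------------------------------------------------
# subset (USRCAT-style) fingerprints

@dataclass(frozen=True)
class AtomTypePredicate:
    """Named deterministic test selecting a subset of atoms."""

    name: str
    matcher: Callable[[AtomRecord, Molecule], bool]

    def select(self, molecule: Molecule) -> list[int]:
        return [i for i, a in enumerate(molecule.atoms) if self.matcher(a, molecule)]


def _is_hydrophobic(atom: AtomRecord, _mol: Molecule) -> bool:
    return atom.element_symbol in {"C", "F", "Cl", "Br", "I"}


def _is_donor(atom: AtomRecord, _mol: Molecule) -> bool:
    return atom.element_symbol in {"N", "O"}


def _is_acceptor(atom: AtomRecord, _mol: Molecule) -> bool:
    return atom.element_symbol in {"N", "O", "F"}


def _is_aromatic(atom: AtomRecord, _mol: Molecule) -> bool:
    return bool(atom.extra_features.get("aromatic", 0.0))


#: Simple element-based predicate set (explicitly NOT the Credo SMARTS
#: types): hydrophobic = carbon + halogens, donor = N/O, acceptor = N/O/F,
#: aromatic = passthrough of a user-supplied per-atom "aromatic" flag.
DEFAULT_PREDICATES: tuple[AtomTypePredicate, ...] = (
    AtomTypePredicate("hydrophobic", _is_hydrophobic),
    AtomTypePredicate("aromatic", _is_aromatic),
    AtomTypePredicate("donor", _is_donor),
    AtomTypePredicate("acceptor", _is_acceptor),
)


def _submolecule(molecule: Molecule, indices: Sequence[int]) -> Molecule:
    return Molecule([molecule.atoms[i] for i in indices], name=molecule.name)


def subset_fingerprint(
    molecule: Molecule,
    predicates: Sequence[AtomTypePredicate] = DEFAULT_PREDICATES,
    engine: str = "usr",
    skewness_convention: str = "standardized",
) -> Fingerprint:
    """USRCAT-layout fingerprint: all-atom block + one block per predicate.

    ``engine="usr"`` uses the heuristic atom-anchored reference points,
    ``engine="hsr"`` the deterministic PCA frame (pure-3D), each yielding a
    12-number block; a predicate matching no atoms contributes 12 zeros so
    the length stays 12 * (1 + number of predicates).
    """
    if engine not in ("usr", "hsr"):
        raise ValueError(f"unknown engine {engine!r} (expected 'usr' or 'hsr')")

    def block(mol: Molecule) -> np.ndarray:
        if engine == "usr":
            return usr_fingerprint(mol, skewness_convention).values
        return molecule_fingerprint(
            mol, scheme="3d", skewness_convention=skewness_convention
        ).values

    blocks = [block(molecule)]
    for predicate in predicates:
        indices = predicate.select(molecule)
        if indices:
            blocks.append(block(_submolecule(molecule, indices)))
        else:
            blocks.append(np.zeros(12))
    return Fingerprint(
        values=np.concatenate(blocks),
        n_dims=3,
        scheme_name=f"subset[{engine}]x{len(predicates)}",
        method_tag="USRCAT_EMU",
        name=molecule.name,
    )


def electroshape_fingerprint(molecule: Molecule, **options) -> Fingerprint:
    """PCA-frame fingerprint on 3D + unscaled partial charge (4D, 15 numbers).

    Partial charges must be supplied per atom (feature table column
    ``partial_charge``); no charge model is computed here.
    """
    return molecule_fingerprint(
        molecule, scheme="electroshape4d", method_tag="ELECTROSHAPE_EMU", **options
    )


def enrichment_factor(
    active_scores: Sequence[float], decoy_scores: Sequence[float], fraction: float
) -> float:
    """Virtual-screening enrichment factor at a top fraction.

    Ranks all scores descending and returns the ratio of the active rate in
    the top ``fraction`` to the active rate overall.  Ties are broken with
    actives ranked after decoys (conservative).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    actives = np.asarray(active_scores, float)
    decoys = np.asarray(decoy_scores, float)
    n_total = actives.size + decoys.size
    if actives.size == 0 or n_total == 0:
        raise ValueError("need at least one active and one score")
    labels = np.concatenate([np.ones(actives.size), np.zeros(decoys.size)])
    scores = np.concatenate([actives, decoys])
    order = np.lexsort((labels, -scores))  # descending score, decoys first on ties
    n_top = max(1, int(np.floor(fraction * n_total)))
    found = float(labels[order][:n_top].sum())
    return (found / n_top) / (actives.size / n_total)
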