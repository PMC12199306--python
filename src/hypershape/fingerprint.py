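"""Reference points, distance distributions and moment fingerprints.

Given an oriented PC frame of an N-dimensional hypershape, N+1 reference
points are placed: one at the geometrical centre (the origin of the PC
coordinate system) and one on each PC at the largest positive projection
of the atoms onto that axis.  The Euclidean distances (in N-space) from
each reference point to every atom form N+1 distance distributions, and
the first three statistical moments of each — mean, standard deviation,
skewness — are concatenated, centre triplet first and then per PC in
order of significance, into an ordered fingerprint of 3(N+1) numbers
(21 for the default 6D scheme, 12 for pure 3D).

Because the reference points lie on the PCs rather than on atoms, the
fingerprint varies continuously under smooth coordinate changes — the
moment-based alternative to heuristic atom-anchored reference points,
whose identity can switch abruptly between conformers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .frame import DEFAULT_SYMMETRY_TOLERANCE, PCFrame, build_frame
from .io import Molecule
from .schemes import Hypershape, build_hypershape, get_scheme

__all__ = [
    "MomentTriplet",
    "Fingerprint",
    "reference_points",
    "distance_distributions",
    "moment_triplet",
    "hsr_fingerprint",
    "fingerprints_to_frame",
    "fingerprints_to_csv",
    "fingerprints_to_json",
]

#: skewness conventions: standardized third moment, or the cube root of the
#: third central moment used by parts of the USR literature
SKEWNESS_CONVENTIONS = ("standardized", "cbrt")

_VAR_EPS = 1e-24


@dataclass(frozen=True)
class MomentTriplet:
    """(mean, standard deviation, skewness) of one distance distribution."""

    mean: float
    std: float
    skewness: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mean, self.std, self.skewness)


@dataclass
class Fingerprint:
    """Ordered moment vector plus the metadata needed for safe comparison."""

    values: np.ndarray
    n_dims: int
    scheme_name: str
    method_tag: str = "HSR"
    chirality_enforced: bool = False
    name: str = ""
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("fingerprint values must be a flat vector")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def metadata_key(self) -> tuple:
        """Comparability key: two fingerprints score only if these match."""
        return (len(self.values), self.method_tag, self.scheme_name, self.chirality_enforced)


def moment_triplet(distances: Sequence[float], convention: str = "standardized") -> MomentTriplet:
    """First three moments of a distance distribution.

    mean = arithmetic mean; std = population standard deviation; skewness
    is the sign-preserving standardized third moment m3 / m2**1.5 (or, under
    the "cbrt" convention, the cube root of the third central moment).
    A zero-variance distribution has skewness 0 by declared convention.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("moment_triplet needs a non-empty 1-D list of distances")
    if convention not in SKEWNESS_CONVENTIONS:
        raise ValueError(f"unknown skewness convention {convention!r}")
    mean = float(d.mean())
    centered = d - mean
    m2 = float(np.mean(centered**2))
    m3 = float(np.mean(centered**3))
    std = float(np.sqrt(m2))
    if m2 <= _VAR_EPS * max(1.0, mean * mean):
        return MomentTriplet(mean, 0.0, 0.0)
    if convention == "standardized":
        skew = m3 / m2**1.5
    else:
        skew = float(np.cbrt(m3))
    return MomentTriplet(mean, std, skew)


def reference_points(frame: PCFrame, scale: float = 1.0) -> np.ndarray:
    """(N+1) x N array of reference points in PC coordinates.

    Row 0 is the geometrical centre (the PC-frame origin); row k places a
    point on axis k-1 at ``scale`` times the largest positive projection of
    the atoms on that axis.  A degenerate axis (max projection 0) leaves
    its point at the origin, duplicating the centre so the fingerprint
    keeps its fixed length.
    """
    n = frame.n_dims
    refs = np.zeros((n + 1, n))
    max_scores = frame.scores.max(axis=0)
    for k in range(n):
        refs[k + 1, k] = scale * max(float(max_scores[k]), 0.0)
    return refs


def distance_distributions(scores: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """(N+1) x A matrix of Euclidean distances from each reference point."""
    return cdist(np.asarray(refs, float), np.asarray(scores, float))


def hsr_fingerprint(
    hypershape: Hypershape,
    chirality: bool = False,
    symmetry_tolerance: float = DEFAULT_SYMMETRY_TOLERANCE,
    skewness_convention: str = "standardized",
    reference_scale: float = 1.0,
    method_tag: str = "HSR",
    name: str = "",
) -> Fingerprint:
    """Full pipeline: frame -> reference points -> distances -> moments."""
    frame = build_frame(hypershape, tolerance=symmetry_tolerance, chirality=chirality)
    refs = reference_points(frame, scale=reference_scale)
    dists = distance_distributions(frame.scores, refs)
    triplets = [moment_triplet(row, skewness_convention) for row in dists]
    values = np.concatenate([t.as_tuple() for t in triplets])
    notes = []
    if frame.undetermined_axes:
        notes.append(f"undetermined axes: {sorted(frame.undetermined_axes)}")
    if frame.degenerate:
        notes.append("degenerate frame (no variance)")
    if chirality and not frame.chirality_enforced:
        notes.append("chirality requested but not applicable")
    return Fingerprint(
        values=values,
        n_dims=hypershape.n_dims,
        scheme_name=hypershape.scheme_name,
        method_tag=method_tag,
        chirality_enforced=frame.chirality_enforced,
        name=name,
        notes=tuple(notes),
    )


def molecule_fingerprint(
    molecule: Molecule,
    scheme="default6d",
    **options,
) -> Fingerprint:
    """Convenience: build the hypershape for ``molecule`` and fingerprint it."""
    shape = build_hypershape(molecule, get_scheme(scheme))
    return hsr_fingerprint(shape, name=molecule.name, **options)


# ---------------------------------------------------------------------------
# serialization

def fingerprints_to_frame(fps: Iterable[Fingerprint]) -> pd.DataFrame:
    """Tabulate fingerprints: name/method/dims metadata plus value columns."""
    rows = []
    for fp in fps:
        row = {
            "name": fp.name,
            "method": fp.method_tag,
            "n_dims": fp.n_dims,
            "scheme": fp.scheme_name,
            "chirality": fp.chirality_enforced,
        }
        row.update({f"v{i:02d}": v for i, v in enumerate(fp.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def fingerprints_to_csv(fps: Iterable[Fingerprint], path: str | Path) -> None:
    fingerprints_to_frame(fps).to_csv(path, index=False)


def fingerprints_to_json(fps: Iterable[Fingerprint], path: str | Path) -> None:
    payload = [
        {
            "name": fp.name,
            "method": fp.method_tag,
            "n_dims": fp.n_dims,
            "scheme": fp.scheme_name,
            "chirality": fp.chirality_enforced,
            "notes": list(fp.notes),
            "values": [float(v) for v in fp.values],
        }
        for fp in fps
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
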