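"""Feature schemes: turning a molecule into an A x N hypershape matrix.

A *hypershape* is a molecule viewed as a point cloud in N dimensions,
N = 3 + F: the three Cartesian coordinates plus F per-atom feature
dimensions.  A :class:`FeatureScheme` names the F extractors (and optional
per-dimension scalers) that build those extra columns.

The default 6D scheme augments the coordinates with three transforms of
basic atomic attributes, chosen so their magnitudes resemble centred
coordinates of small/mid-size molecules:

* ``F1 = sqrt(p)`` — square root of the proton count,
* ``F2 = sign(n - n_ci) * sqrt(|n - n_ci|)`` — signed square root of the
  neutron excess over the element's most common isotope,
* ``F3 = q`` — the formal charge.

Feature values are used raw by default (the unit is absorbed by an implicit
1/unit conversion constant); any rescaling must be applied consistently
across the whole set of molecules being compared, which is why autoscaling
is offered only as an explicit utility over a pooled molecule set, never
per molecule (per-molecule autoscaling destroys absolute information — it
would, for instance, erase the proton-count distinction between PH3 and
NH3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import yaml

from .errors import FeatureError
from .io import AtomRecord, Molecule, most_common_mass_number

__all__ = [
    "FeatureScheme",
    "Hypershape",
    "default_features",
    "build_hypershape",
    "get_scheme",
    "scheme_from_config",
    "autoscale_hypershapes",
]

Extractor = Callable[[AtomRecord], float]
Scaler = Callable[[float], float]


@dataclass(frozen=True)
class FeatureScheme:
    """Named, ordered list of per-atom feature extractors.

    The same scheme instance must be applied to every molecule in a
    comparison set; this is enforced downstream by the fingerprint
    metadata check at scoring time.
    """

    name: str
    extractors: tuple[tuple[str, Extractor], ...] = ()
    scalers: tuple[Scaler | None, ...] = ()

    @property
    def n_dims(self) -> int:
        return 3 + len(self.extractors)

    @property
    def dimension_names(self) -> list[str]:
        return ["x", "y", "z"] + [name for name, _ in self.extractors]


@dataclass
class Hypershape:
    """A x N matrix of one molecule plus dimension metadata."""

    matrix: np.ndarray
    dimension_names: list[str]
    scheme_name: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("hypershape matrix must be 2-D")
        if self.matrix.shape[1] != len(self.dimension_names):
            raise ValueError("dimension_names length must match matrix width")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("hypershape entries must be finite")

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_dims(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# default atomic features

def sqrt_protons(atom: AtomRecord) -> float:
    """F1 = sqrt(p)."""
    if atom.atomic_number < 1:
        raise FeatureError(
            f"proton-count feature undefined for dummy atom {atom.element_symbol!r}"
        )
    return math.sqrt(atom.atomic_number)


def signed_sqrt_neutron_excess(atom: AtomRecord) -> float:
    """F2 = sign(n - n_ci) * sqrt(|n - n_ci|).

    ``n`` is the atom's neutron count, ``n_ci`` that of the element's most
    common isotope, so unlabeled atoms score exactly 0.
    """
    n = atom.neutron_count
    n_ci = most_common_mass_number(atom.atomic_number) - atom.atomic_number
    delta = n - n_ci
    return math.copysign(math.sqrt(abs(delta)), delta) if delta else 0.0


def formal_charge(atom: AtomRecord) -> float:
    """F3 = q, the formal charge."""
    return float(atom.formal_charge)


def default_features(atom: AtomRecord) -> tuple[float, float, float]:
    """(F1, F2, F3) of the default 6D scheme for one atom."""
    return (
        sqrt_protons(atom),
        signed_sqrt_neutron_excess(atom),
        formal_charge(atom),
    )


def _table_feature(column: str) -> Extractor:
    def extract(atom: AtomRecord) -> float:
        try:
            return float(atom.extra_features[column])
        except KeyError:
            raise FeatureError(
                f"atom {atom.element_symbol!r} lacks user feature {column!r}"
            ) from None

    extract.__name__ = f"feature_{column}"
    return extract


_BUILTIN_EXTRACTORS: dict[str, Extractor] = {
    "sqrt_protons": sqrt_protons,
    "signed_sqrt_neutron_excess": signed_sqrt_neutron_excess,
    "formal_charge": formal_charge,
}

_BUILTIN_SCHEMES: dict[str, FeatureScheme] = {
    "3d": FeatureScheme("3d"),
    "4d": FeatureScheme("4d", (("sqrt_protons", sqrt_protons),)),
    "5d_isotope": FeatureScheme(
        "5d_isotope",
        (
            ("sqrt_protons", sqrt_protons),
            ("neutron_excess", signed_sqrt_neutron_excess),
        ),
    ),
    "5d_charge": FeatureScheme(
        "5d_charge",
        (
            ("sqrt_protons", sqrt_protons),
            ("formal_charge", formal_charge),
        ),
    ),
    "default6d": FeatureScheme(
        "default6d",
        (
            ("sqrt_protons", sqrt_protons),
            ("neutron_excess", signed_sqrt_neutron_excess),
            ("formal_charge", formal_charge),
        ),
    ),
    "electroshape4d": FeatureScheme(
        "electroshape4d", (("partial_charge", _table_feature("partial_charge")),)
    ),
}


def get_scheme(name_or_scheme: str | FeatureScheme) -> FeatureScheme:
    """Resolve a built-in scheme name ("3d", "default6d", ...) or pass through."""
    if isinstance(name_or_scheme, FeatureScheme):
        return name_or_scheme
    try:
        return _BUILTIN_SCHEMES[name_or_scheme]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name_or_scheme!r}; built-ins: "
            f"{sorted(_BUILTIN_SCHEMES)}"
        ) from None


_NAMED_SCALERS: dict[str, Scaler] = {
    "identity": lambda v: v,
    "sqrt": lambda v: math.copysign(math.sqrt(abs(v)), v),
    "abs": abs,
    "negate": lambda v: -v,
}


def _resolve_scaler(spec: str | float | None) -> Scaler | None:
    if spec is None or spec == "identity":
        return None
    if isinstance(spec, str):
        if spec.startswith("scale:"):
            factor = float(spec.split(":", 1)[1])
            return lambda v: factor * v
        if spec in _NAMED_SCALERS:
            return _NAMED_SCALERS[spec]
        raise ValueError(f"unknown scaler {spec!r}")
    factor = float(spec)
    return lambda v: factor * v


def scheme_from_config(source: str | dict) -> FeatureScheme:
    """Build a scheme from a YAML string/dict.

    Layout::

        name: my_scheme
        features:
          - extractor: sqrt_protons        # built-in id, or
          - column: partial_charge         # feature-table column reference
            scaler: "scale:25.0"           # optional; also sqrt/abs/identity

    """
    cfg = yaml.safe_load(source) if isinstance(source, str) else source
    extractors: list[tuple[str, Extractor]] = []
    scalers: list[Scaler | None] = []
    for entry in cfg.get("features", []):
        if "extractor" in entry:
            ident = entry["extractor"]
            fn = _BUILTIN_EXTRACTORS.get(ident)
            if fn is None:
                raise ValueError(f"unknown extractor id {ident!r}")
            dim_name = entry.get("name", ident)
        elif "column" in entry:
            ident = entry["column"]
            fn = _table_feature(ident)
            dim_name = entry.get("name", ident)
        else:
            raise ValueError("feature entry needs 'extractor' or 'column'")
        extractors.append((dim_name, fn))
        scalers.append(_resolve_scaler(entry.get("scaler")))
    return FeatureScheme(
        name=str(cfg.get("name", "custom")),
        extractors=tuple(extractors),
        scalers=tuple(scalers),
    )


def build_hypershape(molecule: Molecule, scheme: FeatureScheme | str = "default6d") -> Hypershape:
    """Assemble the A x N hypershape matrix of one molecule.

    Row i is (x, y, z, f1(atom_i), ..., fF(atom_i)), with each feature
    passed through its per-dimension scaler (identity by default).
    """
    scheme = get_scheme(scheme)
    coords = molecule.coordinates
    n_extra = len(scheme.extractors)
    matrix = np.empty((len(molecule), 3 + n_extra), dtype=float)
    matrix[:, :3] = coords
    scalers = scheme.scalers or (None,) * n_extra
    for j, (dim_name, extractor) in enumerate(scheme.extractors):
        scaler = scalers[j] if j < len(scalers) else None
        for i, atom in enumerate(molecule.atoms):
            try:
                value = float(extractor(atom))
            except FeatureError:
                raise
            except Exception as exc:
                raise FeatureError(
                    f"extractor for dimension {dim_name!r} failed on atom {i}: {exc}"
                ) from exc
            if scaler is not None:
                value = scaler(value)
            if not math.isfinite(value):
                raise FeatureError(
                    f"non-finite value for dimension {dim_name!r} on atom {i}"
                )
            matrix[i, 3 + j] = value
    return Hypershape(matrix, scheme.dimension_names, scheme.name)


def autoscale_hypershapes(shapes: Sequence[Hypershape]) -> list[Hypershape]:
    """Mean-centre and scale to unit variance per dimension over a pooled set.

    The statistics are computed across *all atoms of all molecules* so that
    relative information between molecules is preserved; zero-variance
    dimensions are centred but left unscaled.
    """
    if not shapes:
        return []
    names = shapes[0].dimension_names
    for s in shapes[1:]:
        if s.dimension_names != names:
            raise ValueError("autoscaling requires a homogeneous scheme across the set")
    pooled = np.vstack([s.matrix for s in shapes])
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return [
        Hypershape((s.matrix - mean) / std, list(names), s.scheme_name + "+autoscaled")
        for s in shapes
    ]
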