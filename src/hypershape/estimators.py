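"""scikit-learn compatible fingerprinting transformers.

Each transformer maps a list of :class:`~hypershape.io.Molecule` records to
a fixed-width numpy array of fingerprint components, following the
featurizer pattern of packages like scikit-mol: ``fit`` validates
parameters and freezes the output width, ``transform`` vectorizes the
per-molecule computation, and the fitted attributes carry trailing
underscores.  The transformers compose with sklearn pipelines and model
selection out of the box (``get_params``/``set_params``/``clone``).

``SimilaritySearch`` turns any fingerprinter into a library-screening
estimator: ``fit`` stores the fingerprints of a reference library and
``transform`` returns the inverse-scaled-Manhattan similarity of each
query against every library entry.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .baselines import (
    DEFAULT_PREDICATES,
    csr_fingerprint,
    optiso_fingerprint,
    subset_fingerprint,
    usr_fingerprint,
)
from .fingerprint import Fingerprint, hsr_fingerprint
from .frame import DEFAULT_SYMMETRY_TOLERANCE
from .io import Molecule
from .schemes import build_hypershape, get_scheme
from .similarity import similarity_score

__all__ = [
    "HSRFingerprinter",
    "USRFingerprinter",
    "CSRFingerprinter",
    "OptIsoFingerprinter",
    "SubsetFingerprinter",
    "SimilaritySearch",
]


def _check_molecules(X) -> list[Molecule]:
    mols = list(X)
    if not mols:
        raise ValueError("expected a non-empty sequence of Molecule records")
    for m in mols:
        if not isinstance(m, Molecule):
            raise TypeError(f"expected Molecule, got {type(m).__name__}")
    return mols


class _BaseFingerprinter(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing; subclasses implement fingerprint()."""

    def fit(self, X, y=None):
        self._validate_params_()
        return self

    def _validate_params_(self) -> None:  # pragma: no cover - overridden
        pass

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        raise NotImplementedError

    def fingerprints(self, X) -> list[Fingerprint]:
        """Fingerprint objects (values + comparability metadata) per molecule."""
        return [self.fingerprint(m) for m in _check_molecules(X)]

    def transform(self, X) -> np.ndarray:
        fps = self.fingerprints(X)
        return np.vstack([fp.values for fp in fps])


class HSRFingerprinter(_BaseFingerprinter):
    """PCA-frame moment fingerprints of N-dimensional hypershapes.

    Parameters
    ----------
    scheme : str or FeatureScheme, default "default6d"
        Feature scheme building the hypershape ("3d", "4d", "5d_isotope",
        "5d_charge", "default6d", "electroshape4d", or a custom scheme).
    chirality : bool, default False
        Enforce determinant +1 frames so enantiomers score below 1.  Off
        by default: it is meaningful only when the compared hypershapes
        all have a full set of significant, non-mirror-symmetric PCs.
    symmetry_tolerance : float, default 1e-4
        Relative tolerance for detecting symmetric +/- projection pairs in
        the sign-orientation cascade.
    skewness_convention : {"standardized", "cbrt"}
        Standardized third moment (default) or the cube root of the third
        central moment used in parts of the USR literature.
    reference_scale : float, default 1.0
        Multiplier on the distance of the non-centre reference points from
        the centre (1.0 places each at the largest projection).
    """

    def __init__(
        self,
        scheme="default6d",
        chirality: bool = False,
        symmetry_tolerance: float = DEFAULT_SYMMETRY_TOLERANCE,
        skewness_convention: str = "standardized",
        reference_scale: float = 1.0,
    ):
        self.scheme = scheme
        self.chirality = chirality
        self.symmetry_tolerance = symmetry_tolerance
        self.skewness_convention = skewness_convention
        self.reference_scale = reference_scale

    def _validate_params_(self) -> None:
        self.scheme_ = get_scheme(self.scheme)
        self.n_dims_ = self.scheme_.n_dims
        self.n_features_out_ = 3 * (self.n_dims_ + 1)

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        if not hasattr(self, "scheme_"):
            self._validate_params_()
        shape = build_hypershape(molecule, self.scheme_)
        return hsr_fingerprint(
            shape,
            chirality=self.chirality,
            symmetry_tolerance=self.symmetry_tolerance,
            skewness_convention=self.skewness_convention,
            reference_scale=self.reference_scale,
            name=molecule.name,
        )


class USRFingerprinter(_BaseFingerprinter):
    """Classic atom-anchored USR 12-number fingerprints."""

    def __init__(self, skewness_convention: str = "standardized"):
        self.skewness_convention = skewness_convention

    def _validate_params_(self) -> None:
        self.n_features_out_ = 12

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        return usr_fingerprint(molecule, self.skewness_convention)


class CSRFingerprinter(_BaseFingerprinter):
    """Chirality-sensitive USR variant with a cross-product reference point."""

    def __init__(self, skewness_convention: str = "standardized"):
        self.skewness_convention = skewness_convention

    def _validate_params_(self) -> None:
        self.n_features_out_ = 12

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        return csr_fingerprint(molecule, self.skewness_convention)


class OptIsoFingerprinter(_BaseFingerprinter):
    """USR plus a scalar-triple-product 13th descriptor (K = 13)."""

    def __init__(self, skewness_convention: str = "standardized"):
        self.skewness_convention = skewness_convention

    def _validate_params_(self) -> None:
        self.n_features_out_ = 13

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        return optiso_fingerprint(molecule, self.skewness_convention)


class SubsetFingerprinter(_BaseFingerprinter):
    """USRCAT-layout subset fingerprints (all atoms + per-type blocks)."""

    def __init__(
        self,
        predicates=DEFAULT_PREDICATES,
        engine: str = "usr",
        skewness_convention: str = "standardized",
    ):
        self.predicates = predicates
        self.engine = engine
        self.skewness_convention = skewness_convention

    def _validate_params_(self) -> None:
        if self.engine not in ("usr", "hsr"):
            raise ValueError(f"unknown engine {self.engine!r}")
        self.n_features_out_ = 12 * (1 + len(self.predicates))

    def fingerprint(self, molecule: Molecule) -> Fingerprint:
        return subset_fingerprint(
            molecule, self.predicates, self.engine, self.skewness_convention
        )


class SimilaritySearch(TransformerMixin, BaseEstimator):
    """Score queries against a fingerprinted reference library.

    ``fit(library)`` fingerprints the library molecules; ``transform(X)``
    returns an (n_queries, n_library) matrix of similarity scores.
    """

    def __init__(self, fingerprinter=None):
        self.fingerprinter = fingerprinter

    def fit(self, X, y=None):
        fingerprinter = self.fingerprinter or HSRFingerprinter()
        fingerprinter.fit(X)
        self.fingerprinter_ = fingerprinter
        self.library_fingerprints_ = fingerprinter.fingerprints(X)
        return self

    def transform(self, X) -> np.ndarray:
        queries = self.fingerprinter_.fingerprints(X)
        matrix = np.empty((len(queries), len(self.library_fingerprints_)))
        for i, q in enumerate(queries):
            for j, t in enumerate(self.library_fingerprints_):
                matrix[i, j] = similarity_score(q, t).score
        return matrix
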