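"""Deterministic principal-component reference frames.

Eigenvectors of a covariance matrix are defined only up to sign, so a PCA
basis cannot by itself serve as a reproducible reference frame.  This
module removes the ambiguity with a sign-orientation cascade: each
principal component (PC) is oriented so that the largest projection of the
centred hypershape onto it is positive.  When the largest projection
belongs to a symmetric +/- pair the decision falls to the next largest
projection, and so on; if every projection pairs off, the cloud has a
mirror plane orthogonal to that PC (e.g. the molecular axis of acetylene)
and the sign genuinely does not matter — the axis is recorded as
*undetermined* and left unflipped.

Bookkeeping for chirality: with ``det_i`` the determinant of the raw
eigenvector matrix and ``n_c`` the number of sign flips applied by the
cascade, the oriented determinant satisfies ``det_f = det_i * (-1)**n_c``.
Mirror-image molecules end up with mirror-image frames (identical
fingerprints); optional chirality enforcement flips the PC with the most
skewed projection scores whenever ``det_f == -1`` so every frame has
determinant +1 and enantiomers acquire different reference points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FrameError
from .schemes import Hypershape

__all__ = ["PCFrame", "center", "principal_axes", "orient_axes", "enforce_chirality", "build_frame"]

#: default relative tolerance for symmetric +/- projection pairs
DEFAULT_SYMMETRY_TOLERANCE = 1e-4

_ORTHO_TOL = 1e-10


@dataclass
class PCFrame:
    """Oriented principal-component frame of one hypershape."""

    axes: np.ndarray            # N x N, columns = oriented PCs
    eigenvalues: np.ndarray     # N, descending |value|
    scores: np.ndarray          # A x N projections of the centred cloud
    centroid: np.ndarray        # N
    n_c: int = 0                # sign flips applied during orientation
    det_i: int = 1              # determinant before orientation
    det_f: int = 1              # determinant after orientation
    chirality_enforced: bool = False
    undetermined_axes: frozenset[int] = field(default_factory=frozenset)
    degenerate: bool = False    # True when the cloud had no variance at all

    @property
    def n_dims(self) -> int:
        return self.axes.shape[0]


def center(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the column means; returns (centred matrix, centroid)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise FrameError("expected a non-empty 2-D matrix")
    centroid = matrix.mean(axis=0)
    return matrix - centroid, centroid


def _sign_of_det(axes: np.ndarray) -> int:
    d = float(np.linalg.det(axes))
    return 1 if d >= 0 else -1


def principal_axes(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigenvectors/eigenvalues of the population covariance of a centred cloud.

    Returns (axes, eigenvalues, degenerate).  Columns of ``axes`` are unit
    eigenvectors ordered by descending |eigenvalue|; ties are broken by the
    larger maximum |projection| and then by original column order, so the
    basis is deterministic even for symmetric clouds.  A single point or
    all-identical rows yield an identity basis, zero eigenvalues and
    ``degenerate=True`` rather than an error.
    """
    centered = np.asarray(centered, dtype=float)
    a, n = centered.shape
    cov = centered.T @ centered / a  # population convention (divide by A)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    scale = max(1.0, float(np.max(np.abs(eigenvalues))))
    if np.all(np.abs(eigenvalues) <= 1e-14 * scale) or a == 1:
        return np.eye(n), np.zeros(n), True

    # group eigenvalues equal within tolerance, then order groups by |value|
    scores = centered @ eigenvectors
    max_abs_score = np.max(np.abs(scores), axis=0)
    tol = 1e-9 * scale
    order = sorted(
        range(n),
        key=lambda j: (
            -round(abs(eigenvalues[j]) / tol) if tol else 0,
            -max_abs_score[j],
            j,
        ),
    )
    return eigenvectors[:, order], eigenvalues[order], False


def _axis_orientation(projections: np.ndarray, tolerance: float) -> int:
    """Sign decision for one axis: +1 keep, -1 flip, 0 undetermined.

    Walks the projections in descending magnitude, skipping symmetric
    +/- pairs (|a + b| <= tol * max(1, |a|)) and near-zero values, until an
    unpaired projection decides the sign.
    """
    order = np.argsort(-np.abs(projections), kind="stable")
    vals = projections[order]
    used = np.zeros(len(vals), dtype=bool)
    for i, a in enumerate(vals):
        if used[i]:
            continue
        if abs(a) <= tolerance:
            return 0  # remaining projections are all ~0
        partner = None
        pair_tol = tolerance * max(1.0, abs(a))
        for j in range(i + 1, len(vals)):
            if not used[j] and abs(a + vals[j]) <= pair_tol:
                partner = j
                break
        if partner is not None:
            used[i] = used[partner] = True
            continue
        return 1 if a > 0 else -1
    return 0


def orient_axes(
    eigenvectors: np.ndarray,
    eigenvalues: np.ndarray,
    scores: np.ndarray,
    centroid: np.ndarray,
    tolerance: float = DEFAULT_SYMMETRY_TOLERANCE,
    degenerate: bool = False,
) -> PCFrame:
    """Apply the sign-orientation cascade to a PCA basis.

    ``scores`` must be the projections of the centred cloud onto
    ``eigenvectors`` (columns).  Flipped axes increment ``n_c``; axes with
    fully symmetric projections are recorded in ``undetermined_axes`` and
    left alone.  The determinant identity det_f = det_i * (-1)**n_c is
    asserted on every call.
    """
    axes = np.array(eigenvectors, dtype=float)
    n = axes.shape[0]
    if axes.shape != (n, n) or not np.allclose(axes.T @ axes, np.eye(n), atol=1e-8):
        raise FrameError("eigenvector matrix must be square and orthonormal")
    scores = np.array(scores, dtype=float)
    det_i = _sign_of_det(axes)
    n_c = 0
    undetermined: set[int] = set()
    for k in range(n):
        decision = _axis_orientation(scores[:, k], tolerance)
        if decision == 0:
            undetermined.add(k)
        elif decision < 0:
            axes[:, k] = -axes[:, k]
            scores[:, k] = -scores[:, k]
            n_c += 1
    det_f = _sign_of_det(axes)
    if det_f != det_i * (-1) ** n_c:  # pragma: no cover - internal consistency
        raise FrameError("determinant bookkeeping violated: det_f != det_i * (-1)^n_c")
    return PCFrame(
        axes=axes,
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        scores=scores,
        centroid=np.asarray(centroid, dtype=float),
        n_c=n_c,
        det_i=det_i,
        det_f=det_f,
        undetermined_axes=frozenset(undetermined),
        degenerate=degenerate,
    )


def enforce_chirality(frame: PCFrame) -> PCFrame:
    """Impose determinant +1 on an oriented frame (enantiomer distinction).

    If ``det_f`` is already +1 the frame is returned unchanged apart from
    the ``chirality_enforced`` flag.  Otherwise the axis whose projection
    scores have the largest |standardized skewness| is flipped (ties go to
    the lowest axis index).  When any axis is undetermined — including
    zero-variance axes, whose projections are all zero — the cloud has a
    mirror symmetry or too few significant PCs for a determinant-based
    orientation to be meaningful, so chirality is refused with a warning
    and the frame is returned untouched.
    """
    if frame.undetermined_axes or frame.degenerate:
        warnings.warn(
            "chirality not applicable: frame has undetermined or zero-variance "
            f"axes {sorted(frame.undetermined_axes)}; returning frame unchanged",
            stacklevel=2,
        )
        return frame
    if frame.det_f == 1:
        frame.chirality_enforced = True
        return frame
    skewness = np.abs(stats.skew(frame.scores, axis=0, bias=True))
    skewness = np.nan_to_num(skewness, nan=0.0)
    axis = int(np.argmax(skewness))  # argmax takes the lowest index on ties
    frame.axes[:, axis] = -frame.axes[:, axis]
    frame.scores[:, axis] = -frame.scores[:, axis]
    frame.n_c += 1
    frame.det_f = _sign_of_det(frame.axes)
    if frame.det_f != frame.det_i * (-1) ** frame.n_c:  # pragma: no cover
        raise FrameError("determinant bookkeeping violated after chirality flip")
    frame.chirality_enforced = True
    return frame


def build_frame(
    hypershape: Hypershape,
    tolerance: float = DEFAULT_SYMMETRY_TOLERANCE,
    chirality: bool = False,
) -> PCFrame:
    """centre -> eigendecompose -> orient (-> enforce chirality)."""
    centered, centroid = center(hypershape.matrix)
    axes, eigenvalues, degenerate = principal_axes(centered)
    scores = centered @ axes
    frame = orient_axes(axes, eigenvalues, scores, centroid, tolerance, degenerate)
    if chirality:
        frame = enforce_chirality(frame)
    return frame
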