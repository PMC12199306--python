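"""Fingerprint comparison: inverse scaled Manhattan similarity.

Two fingerprints q and t of common length K are compared through the
Manhattan distance d_M(q, t) = sum_i |q_i - t_i| and the score

    S_qt = 1 / (1 + d_M / K)   in (0, 1],

where 1 means identical fingerprints.  K is the fingerprint length
(3(N+1) for an N-dimensional hypershape; 12 for USR, 13 for USR:OptIso),
so scores from representations of different dimensionality are normalized
differently and are *not* directly comparable — such pairs raise an error
rather than being scored silently.  For studies that vary dimensionality,
compare raw Manhattan distances instead (``manhattan_distance``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import IncomparableFingerprintsError
from .fingerprint import Fingerprint

__all__ = ["SimilarityResult", "manhattan_distance", "similarity_score", "pairwise_matrix"]


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    manhattan: float
    K: int


def _check_comparable(q: Fingerprint, t: Fingerprint) -> None:
    if q.metadata_key != t.metadata_key:
        raise IncomparableFingerprintsError(
            f"fingerprints are not comparable: "
            f"(len, method, scheme, chirality) {q.metadata_key} vs {t.metadata_key}"
        )


def manhattan_distance(q: Fingerprint, t: Fingerprint) -> float:
    """d_M(q, t) = sum of absolute component differences."""
    _check_comparable(q, t)
    return float(np.sum(np.abs(q.values - t.values)))


def similarity_score(q: Fingerprint, t: Fingerprint) -> SimilarityResult:
    """Inverse scaled Manhattan similarity of two comparable fingerprints."""
    d = manhattan_distance(q, t)
    k = len(q)
    return SimilarityResult(score=1.0 / (1.0 + d / k), manhattan=d, K=k)


def pairwise_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric matrix of pairwise similarity scores (unit diagonal)."""
    n = len(fps)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                _check_comparable(fps[i], fps[j])
            except IncomparableFingerprintsError as exc:
                raise IncomparableFingerprintsError(
                    f"fingerprints {i} ({fps[i].name!r}) and {j} ({fps[j].name!r}): {exc}"
                ) from None
    matrix = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = similarity_score(fps[i], fps[j]).score
            matrix[i, j] = matrix[j, i] = s
    return matrix
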