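"""The four pairwise text-similarity measures and matrix construction.

Cosine similarity (CS) and the Jaccard coefficient (JC) are oriented as
similarities (1 = identical); Euclidean (ED) and Manhattan (MD) distances
are oriented as distances (0 = identical).  CS, ED and MD operate on the
weighted n-gram vectors; JC operates on the n-gram presence sets (binary
support) regardless of the weighting chosen for the vector measures, since
it is defined on finite sets.

The Manhattan distance is the standard city-block sum of absolute
coordinate differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import (
    cosine_similarity,
    euclidean_distances,
    manhattan_distances,
)

from .corpus_io import LabeledMatrix
from .exceptions import UndefinedSimilarityError
from .preprocess import DocTermMatrix

__all__ = [
    "MeasureSpec",
    "MEASURES",
    "cosine",
    "euclidean",
    "manhattan",
    "jaccard",
    "similarity_matrix",
]


@dataclass(frozen=True)
class MeasureSpec:
    name: str
    orientation: str  # "similarity" or "distance"
    input_kind: str  # "vector" or "set"


MEASURES: dict[str, MeasureSpec] = {
    "CS": MeasureSpec("CS", "similarity", "vector"),
    "ED": MeasureSpec("ED", "distance", "vector"),
    "MD": MeasureSpec("MD", "distance", "vector"),
    "JC": MeasureSpec("JC", "similarity", "set"),
}


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must share one dimension, got {x.shape} and {y.shape}")
    return x, y


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two vectors; scale-invariant, and in
    [0, 1] for nonnegative weights."""
    x, y = _check_pair(x, y)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedSimilarityError("cosine undefined for zero-norm vector")
    return float(np.dot(x, y) / (nx * ny))


def euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Straight-line distance between two points in term space."""
    x, y = _check_pair(x, y)
    return float(np.linalg.norm(x - y))


def manhattan(x: np.ndarray, y: np.ndarray) -> float:
    """City-block distance: sum of absolute coordinate differences."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum())


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Intersection over union of two term sets."""
    if not a and not b:
        raise UndefinedSimilarityError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def similarity_matrix(dtm: DocTermMatrix, measure: str | MeasureSpec) -> LabeledMatrix:
    """Pairwise drug x drug matrix under one measure.

    The diagonal is set exactly (1 for similarities, 0 for distances) and
    the result is symmetrized to cancel floating-point asymmetry.
    """
    spec = MEASURES[measure] if isinstance(measure, str) else measure
    if spec.name not in MEASURES:
        raise KeyError(f"unknown measure {spec.name!r}")
    mat = dtm.matrix
    n = len(dtm.doc_labels)

    if spec.name in ("CS", "JC") and dtm.empty_labels:
        raise UndefinedSimilarityError(
            f"{spec.name} undefined for empty documents: {sorted(dtm.empty_labels)}"
        )

    if spec.name == "CS":
        values = cosine_similarity(mat)
        values = np.clip(values, 0.0, 1.0)
    elif spec.name == "ED":
        values = euclidean_distances(mat)
    elif spec.name == "MD":
        values = manhattan_distances(np.asarray(mat.todense()))
    else:  # JC on binary supports
        support = sp.csr_matrix((mat > 0).astype(np.int64))
        sizes = np.asarray(support.sum(axis=1)).ravel()
        inter = np.asarray(support @ support.T.todense(), dtype=float).reshape(n, n)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore"):
            values = np.where(union > 0, inter / np.maximum(union, 1), np.nan)

    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0 if spec.orientation == "similarity" else 0.0)
    return LabeledMatrix(list(dtm.doc_labels), values, spec.orientation)
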