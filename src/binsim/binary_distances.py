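"""Binary dissimilarities over feature-occurrence vectors.

For two samples with occurrence vectors a and b, the 2x2 contingency counts
are n11 (present in both), n10 (only in a), n01 (only in b) and n00 (absent
from both).  Three dissimilarities are built on them:

    Jaccard:  1 - n11 / (n11 + n10 + n01)                  in [0, 1]
    Yule:     2 n10 n01 / (n11 n00 + n10 n01)              in [0, 2]
    Hamming:  (n10 + n01) / (n11 + n10 + n01 + n00)        in [0, 1]

Jaccard ignores joint absences; Hamming counts them as agreement; Yule
contrasts concordant and discordant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "OccurrenceContingency",
    "DistanceMatrix",
    "contingency",
    "jaccard",
    "yule",
    "hamming",
    "distance_matrix",
    "BINARY_METRICS",
]

BINARY_METRICS = ("jaccard", "yule", "hamming")


@dataclass(frozen=True)
class OccurrenceContingency:
    """Pairwise presence/absence counts; n11+n10+n01+n00 = number of features."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with a zero diagonal."""

    sample_ids: tuple
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix must be square and match sample_ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.values, checks=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def contingency(a, b) -> OccurrenceContingency:
    """Occurrence contingency counts of two equal-length {0,1} vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("vectors must be binary (entries 0 or 1)")
    a = a.astype(bool)
    b = b.astype(bool)
    return OccurrenceContingency(
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def jaccard(c: OccurrenceContingency) -> float:
    """Jaccard dissimilarity; undefined when both samples are all-absent."""
    union = c.n11 + c.n10 + c.n01
    if union == 0:
        raise ValueError("Jaccard dissimilarity is undefined for two all-absent vectors")
    return 1.0 - c.n11 / union


def yule(c: OccurrenceContingency) -> float:
    """Yule dissimilarity 2·n10·n01/(n11·n00 + n10·n01), range [0, 2].

    A zero denominator means there is no concordance/discordance evidence;
    0 is returned with a warning.
    """
    denom = c.n11 * c.n00 + c.n10 * c.n01
    if denom == 0:
        warnings.warn("Yule denominator is zero (no discordance evidence); returning 0")
        return 0.0
    return 2.0 * c.n10 * c.n01 / denom


def hamming(c: OccurrenceContingency) -> float:
    """Fraction of features on which the two samples disagree."""
    if c.total == 0:
        raise ValueError("Hamming distance is undefined for zero-length vectors")
    return (c.n10 + c.n01) / c.total


_PAIRWISE = {"jaccard": jaccard, "yule": yule, "hamming": hamming}


def distance_matrix(m, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise sample dissimilarities of a binary or intensity matrix.

    Binary metrics (jaccard, yule, hamming) require a
    :class:`~binsim.pretreatment.BinaryMatrix`; ``euclidean`` requires a
    fully observed numeric matrix (PeakTable, DataFrame or ndarray).
    """
    from .pretreatment import BinaryMatrix  # local import avoids a cycle

    if metric in _PAIRWISE:
        if not isinstance(m, BinaryMatrix):
            raise TypeError(f"metric {metric!r} requires a BinaryMatrix")
        X = m.values
        ids = m.sample_ids
        n = X.shape[0]
        out = np.zeros((n, n))
        fn = _PAIRWISE[metric]
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = fn(contingency(X[i], X[j]))
        return DistanceMatrix(ids, out, metric)
    if metric == "euclidean":
        if hasattr(m, "sample_ids") and hasattr(m, "feature_mz"):
            # PeakTable or BinaryMatrix
            X, ids = np.asarray(m.values, dtype=float), m.sample_ids
        elif isinstance(m, pd.DataFrame):
            X, ids = m.to_numpy(dtype=float), list(m.index)
        else:
            X = np.asarray(m, dtype=float)
            ids = [str(i) for i in range(X.shape[0])]
        if np.isnan(X).any():
            raise ValueError("euclidean distance requires a fully observed matrix")
        return DistanceMatrix(ids, squareform(pdist(X, metric="euclidean")), metric)
    raise ValueError(f"unknown metric {metric!r}")
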