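"""Similarity measures between two entropy matrices.

Four measures are supported: dynamic time warping (DTW) and the Jaccard
dissimilarity (JSC) are distances (smaller = more similar); mutual
information (MI) and the Spearman rank correlation (SCC) are similarities
(larger = more similar).  Matrices are flattened row-major in canonical
BREM order before comparison; MI and JSC first discretize the continuous
entries into equal-width bins over the two matrices' pooled range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "METHODS", "ORIENTATIONS", "SimilarityScore", "SimilarityConfig",
    "dtw_distance", "mutual_information", "spearman_similarity",
    "jaccard_dissimilarity", "score",
]

METHODS = ("DTW", "MI", "SCC", "JSC")
#: smaller-is-more-similar ("distance") vs larger-is-more-similar ("similarity")
ORIENTATIONS = {"DTW": "distance", "MI": "similarity",
                "SCC": "similarity", "JSC": "distance"}


@dataclass(frozen=True)
class SimilarityScore:
    method: str
    value: float
    orientation: str

    @property
    def higher_is_more_similar(self) -> bool:
        return self.orientation == "similarity"


@dataclass(frozen=True)
class SimilarityConfig:
    """Discretization and flattening knobs.

    ``flatten_order`` is "row" (canonical: gamma row first, AE..PSDE within
    a row) or "col"; ``mi_bins`` and ``jsc_bins`` are the equal-width
    histogram bin / quantization level counts used by MI and JSC.
    """

    flatten_order: str = "row"
    mi_bins: int = 5
    jsc_bins: int = 5

    def __post_init__(self) -> None:
        if self.flatten_order not in ("row", "col"):
            raise ValueError("flatten_order must be 'row' or 'col'")
        if self.mi_bins < 2 or self.jsc_bins < 2:
            raise ValueError("bin counts must be >= 2")


def _as_matrix(obj) -> np.ndarray:
    values = getattr(obj, "values", obj)
    return np.atleast_2d(np.asarray(values, dtype=np.float64))


def _flat_pair(a_obj, b_obj, cfg: SimilarityConfig) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_matrix(a_obj), _as_matrix(b_obj)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    order = "C" if cfg.flatten_order == "row" else "F"
    return a.ravel(order=order), b.ravel(order=order)


def _quantize(a: np.ndarray, b: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width binning over the pooled range; returns integer levels."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return np.zeros(len(a), dtype=int), np.zeros(len(b), dtype=int)
    edges = np.linspace(lo, hi, bins + 1)
    la = np.clip(np.digitize(a, edges) - 1, 0, bins - 1)
    lb = np.clip(np.digitize(b, edges) - 1, 0, bins - 1)
    return la, lb


def dtw_distance(a_obj, b_obj,
                 cfg: SimilarityConfig = SimilarityConfig()) -> SimilarityScore:
    """Classical DTW distance with absolute-difference local cost.

    The cumulative cost obeys
    ``C(i,j) = |a_i - b_j| + min(C(i-1,j), C(i,j-1), C(i-1,j-1))`` and the
    returned value is ``C(n,m)``; it is symmetric and 0 iff the flattened
    sequences are identical.  Unlike the other measures, the warping path
    accommodates inputs of different lengths.
    """
    order = "C" if cfg.flatten_order == "row" else "F"
    a = _as_matrix(a_obj).ravel(order=order)
    b = _as_matrix(b_obj).ravel(order=order)
    n, m = len(a), len(b)
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(n):
        cur = np.full(m + 1, np.inf)
        cost = np.abs(a[i] - b)
        for j in range(m):
            cur[j + 1] = cost[j] + min(prev[j], prev[j + 1], cur[j])
        prev = cur
    return SimilarityScore("DTW", float(prev[m]), ORIENTATIONS["DTW"])


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def mutual_information(a_obj, b_obj,
                       cfg: SimilarityConfig = SimilarityConfig()) -> SimilarityScore:
    """Histogram mutual information ``H(A) + H(B) - H(A,B)`` (natural log).

    Both matrices are discretized into ``mi_bins`` equal-width bins over
    their pooled range and the joint histogram pairs co-located entries.
    Constant matrices have zero entropy, hence MI = 0.
    """
    a, b = _flat_pair(a_obj, b_obj, cfg)
    if len(a) < 2:
        raise ValueError("need at least 2 entries for mutual information")
    la, lb = _quantize(a, b, cfg.mi_bins)
    joint = np.zeros((cfg.mi_bins, cfg.mi_bins))
    np.add.at(joint, (la, lb), 1.0)
    h_a = _entropy_from_counts(joint.sum(axis=1))
    h_b = _entropy_from_counts(joint.sum(axis=0))
    h_ab = _entropy_from_counts(joint.ravel())
    value = max(h_a + h_b - h_ab, 0.0)
    return SimilarityScore("MI", value, ORIENTATIONS["MI"])


def spearman_similarity(a_obj, b_obj,
                        cfg: SimilarityConfig = SimilarityConfig()) -> SimilarityScore:
    """Spearman rank correlation of the flattened matrices (average ranks
    for ties); 0 with a warning when either side has zero rank variance."""
    a, b = _flat_pair(a_obj, b_obj, cfg)
    if len(a) < 3:
        raise ValueError("need at least 3 entries for a rank correlation")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("zero rank variance; Spearman correlation set to 0",
                      stacklevel=2)
        return SimilarityScore("SCC", 0.0, ORIENTATIONS["SCC"])
    rho = stats.spearmanr(a, b).statistic
    return SimilarityScore("SCC", float(np.clip(rho, -1.0, 1.0)),
                           ORIENTATIONS["SCC"])


def jaccard_dissimilarity(a_obj, b_obj,
                          cfg: SimilarityConfig = SimilarityConfig()) -> SimilarityScore:
    """Jaccard dissimilarity ``1 - |A & B| / |A | B|`` on quantized sets.

    Each matrix becomes the set of ``(cell position, quantization level)``
    pairs with ``jsc_bins`` equal-width levels over the pooled range, so a
    cell contributes to the intersection iff both matrices quantize it to
    the same level.  0 for identical matrices, 1 for wholly disjoint sets;
    treated as a distance downstream.
    """
    a, b = _flat_pair(a_obj, b_obj, cfg)
    la, lb = _quantize(a, b, cfg.jsc_bins)
    inter = int(np.count_nonzero(la == lb))
    union = 2 * len(a) - inter
    return SimilarityScore("JSC", 1.0 - inter / union, ORIENTATIONS["JSC"])


_DISPATCH = {
    "DTW": dtw_distance,
    "MI": mutual_information,
    "SCC": spearman_similarity,
    "JSC": jaccard_dissimilarity,
}


def score(a_obj, b_obj, method: str,
          cfg: SimilarityConfig = SimilarityConfig()) -> SimilarityScore:
    """Dispatch to one of the four measures by (case-insensitive) name."""
    key = method.upper()
    if key not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return _DISPATCH[key](a_obj, b_obj, cfg)
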