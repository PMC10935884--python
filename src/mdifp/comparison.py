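"""Similarity analysis of aggregated fingerprint sets.

Within one simulation, fingerprints are compared by the number of absolute
bit differences

    N_diff = sum_i |IFP1_i - IFP2_i|        (the Hamming distance).

Between two simulations the column spaces differ and raw difference counts
are no longer comparable, so the Rogers-Tanimoto dissimilarity is used:

    D_RT = 2 (c_TF + c_FT) / (c_TT + c_FF + 2 (c_TF + c_FT))

where c_TT / c_FF count positions set in both / neither vector and
c_TF / c_FT the mismatches; similarity is 1 - D_RT.  Because
c_TF + c_FT = N_diff and c_TT + c_FF = L - N_diff for vectors of length L,
the similarity has the closed form 1 - 2 d / (L + d), which the vectorised
matrix routines exploit.

Cross-set fingerprint pairs are classified as identical (similarity
>= 0.95), similar (0.85 <= s < 0.95) or dissimilar (s < 0.5); pairs in
[0.5, 0.85) belong to no class.  Thresholds are user-adjustable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregation import AggregatedFingerprintSet

__all__ = [
    "ConcordanceCounts",
    "SimilarityThresholds",
    "SimilarityClassification",
    "concordance_counts",
    "n_diff",
    "difference_matrix",
    "rogers_tanimoto_dissimilarity",
    "similarity",
    "cross_set_similarity_matrix",
    "classify",
]


def _as_bits(v) -> np.ndarray:
    arr = np.asarray(v)
    return arr.astype(np.int64).ravel()


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.shape[0]} vs {b.shape[0]}")


@dataclass(frozen=True)
class ConcordanceCounts:
    """Position counts for a bit-vector pair: both on, both off, mismatches."""

    c_tt: int
    c_ff: int
    c_tf: int
    c_ft: int

    @property
    def length(self) -> int:
        return self.c_tt + self.c_ff + self.c_tf + self.c_ft


def concordance_counts(ifp1, ifp2) -> ConcordanceCounts:
    a, b = _as_bits(ifp1), _as_bits(ifp2)
    _check_pair(a, b)
    return ConcordanceCounts(
        int(np.sum((a == 1) & (b == 1))),
        int(np.sum((a == 0) & (b == 0))),
        int(np.sum((a == 1) & (b == 0))),
        int(np.sum((a == 0) & (b == 1))),
    )


def n_diff(ifp1, ifp2) -> int:
    """Number of absolute bit differences (Hamming distance)."""
    a, b = _as_bits(ifp1), _as_bits(ifp2)
    _check_pair(a, b)
    return int(np.abs(a - b).sum())


def rogers_tanimoto_dissimilarity(ifp1, ifp2) -> float:
    """Rogers-Tanimoto dissimilarity in [0, 1]; 0 for identical vectors."""
    c = concordance_counts(ifp1, ifp2)
    if c.length < 1:
        raise ValueError("fingerprints must have length >= 1")
    mismatch = c.c_tf + c.c_ft
    return 2.0 * mismatch / (c.c_tt + c.c_ff + 2.0 * mismatch)


def similarity(ifp1, ifp2) -> float:
    """Rogers-Tanimoto similarity: 1 - dissimilarity."""
    return 1.0 - rogers_tanimoto_dissimilarity(ifp1, ifp2)


def _ifp_matrix(obj) -> np.ndarray:
    if isinstance(obj, AggregatedFingerprintSet):
        return obj.ifps.astype(np.int64)
    return np.asarray(obj, dtype=np.int64)


def _pairwise_hamming(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|X| x |Y| matrix of bit differences via inner products."""
    cross = x @ y.T
    rx = x.sum(axis=1)[:, None]
    ry = y.sum(axis=1)[None, :]
    return rx + ry - 2 * cross


def difference_matrix(agg) -> np.ndarray:
    """Symmetric matrix of pairwise bit differences within one set.

    Accepts an :class:`AggregatedFingerprintSet` or a plain 0/1 matrix;
    rows/columns follow the aggregated id order.
    """
    x = _ifp_matrix(agg)
    return _pairwise_hamming(x, x)


def cross_set_similarity_matrix(
    a: AggregatedFingerprintSet, b: AggregatedFingerprintSet
) -> np.ndarray:
    """|A| x |B| Rogers-Tanimoto similarity over the merged column space.

    Both sets must already share one column list (apply
    :func:`mdifp.core.merge_column_spaces` first); this is enforced because
    matched absent interactions enter the Rogers-Tanimoto denominator and
    silently differing column spaces would corrupt every value.
    """
    if tuple(a.columns) != tuple(b.columns):
        raise ValueError(
            "column spaces differ; apply merge_column_spaces(a, b) before "
            "computing cross-set similarities"
        )
    length = len(a.columns)
    if length < 1:
        raise ValueError("fingerprints must have length >= 1")
    d = _pairwise_hamming(_ifp_matrix(a), _ifp_matrix(b)).astype(np.float64)
    return 1.0 - 2.0 * d / (length + d)


@dataclass(frozen=True)
class SimilarityThresholds:
    """Class boundaries on the similarity scale.

    identical: s >= ``identical``; similar: ``similar_low`` <= s <
    ``identical``; dissimilar: s < ``dissimilar``.
    """

    identical: float = 0.95
    similar_low: float = 0.85
    dissimilar: float = 0.50

    def __post_init__(self) -> None:
        if not 0.5 <= self.similar_low < self.identical <= 1.0:
            raise ValueError(
                "thresholds must satisfy 0.5 <= similar_low < identical <= 1, "
                f"got similar_low={self.similar_low}, identical={self.identical}"
            )
        if not 0.0 < self.dissimilar <= self.similar_low:
            raise ValueError(
                f"dissimilar threshold {self.dissimilar} must lie in "
                f"(0, similar_low]"
            )


CLASS_NAMES = ("identical", "similar", "dissimilar")


@dataclass
class SimilarityClassification:
    """Cross-set class memberships under a threshold triple.

    ``memberships_a[cls][i]`` lists the ids in set B whose similarity to
    fingerprint ``i`` of set A falls in the class range (and symmetrically
    for ``memberships_b``).  ``pair_counts`` counts (A, B) pairs per class
    (plus ``unclassified``); ``membership_counts`` counts fingerprints
    appearing in at least one pair of the class, per side — one
    fingerprint can belong to several classes depending on the reference
    fingerprint, so neither tally needs to sum to the total.
    """

    thresholds: SimilarityThresholds
    shape: tuple[int, int]
    memberships_a: dict[str, dict[int, list[int]]]
    memberships_b: dict[str, dict[int, list[int]]]
    pair_counts: dict[str, int]
    membership_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.shape[0] * self.shape[1]

    def pair_fractions(self) -> dict[str, float]:
        """Per-class share of all |A| x |B| comparisons."""
        total = self.n_pairs
        return {c: self.pair_counts[c] / total for c in self.pair_counts}

    def to_json(self, path=None) -> str:
        payload = {
            "thresholds": {
                "identical": self.thresholds.identical,
                "similar_low": self.thresholds.similar_low,
                "dissimilar": self.thresholds.dissimilar,
            },
            "shape": list(self.shape),
            "pair_counts": self.pair_counts,
            "membership_counts": self.membership_counts,
            "memberships_a": {
                c: {str(i): v for i, v in m.items()}
                for c, m in self.memberships_a.items()
            },
            "memberships_b": {
                c: {str(i): v for i, v in m.items()}
                for c, m in self.memberships_b.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def classify(
    matrix: np.ndarray,
    thresholds: SimilarityThresholds | None = None,
) -> SimilarityClassification:
    """Classify every entry of a cross-set similarity matrix.

    Rows index fingerprints of set A, columns of set B.  Returns both
    pair-level counts and per-side membership counts.
    """
    thresholds = thresholds or SimilarityThresholds()
    sim = np.asarray(matrix, dtype=np.float64)
    if sim.ndim != 2:
        raise ValueError("similarity matrix must be two-dimensional")
    masks = {
        "identical": sim >= thresholds.identical,
        "similar": (sim >= thresholds.similar_low) & (sim < thresholds.identical),
        "dissimilar": sim < thresholds.dissimilar,
    }
    memberships_a: dict[str, dict[int, list[int]]] = {}
    memberships_b: dict[str, dict[int, list[int]]] = {}
    pair_counts: dict[str, int] = {}
    membership_counts: dict[str, dict[str, int]] = {}
    for cls, mask in masks.items():
        ii, jj = np.nonzero(mask)
        ma: dict[int, list[int]] = {}
        mb: dict[int, list[int]] = {}
        for i, j in zip(ii.tolist(), jj.tolist()):
            ma.setdefault(i, []).append(j)
            mb.setdefault(j, []).append(i)
        memberships_a[cls] = ma
        memberships_b[cls] = mb
        pair_counts[cls] = int(mask.sum())
        membership_counts[cls] = {
            "a": len(ma), "b": len(mb), "total": len(ma) + len(mb)
        }
    pair_counts["unclassified"] = int(sim.size - sum(
        pair_counts[c] for c in CLASS_NAMES
    ))
    return SimilarityClassification(
        thresholds, tuple(sim.shape), memberships_a, memberships_b,
        pair_counts, membership_counts,
    )
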