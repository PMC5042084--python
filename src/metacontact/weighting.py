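"""Sequence redundancy weighting and the effective sequence count N_eff.

Large alignments carry many near-duplicate sequences that add no contact
information.  Depth is therefore measured as an *effective* sequence count:
sequences are clustered at a 62% pairwise-identity threshold (the same
threshold used to compile BLOSUM62) with single linkage, and N_eff is the
number of clusters.  Per-sequence weights are 1/(cluster size), so the
weights sum exactly to N_eff; these weights are used by every downstream
frequency and covariation computation.

Pairwise identity between two aligned rows is matches divided by the number
of columns where at least one of the two rows is non-gap; columns gapped in
both are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .msa_io import Alignment, STATE_INDEX, GAP

DEFAULT_IDENTITY_THRESHOLD = 0.62

_GAP_STATE = STATE_INDEX[GAP]


def pairwise_identity(s1: str, s2: str) -> float:
    """Fractional identity of two equal-length aligned strings.

    Denominator: columns where at least one string is non-gap.  Returns 0
    when that denominator is 0 (both strings all-gap).
    """
    if len(s1) != len(s2):
        raise ValueError("aligned strings differ in length")
    matches = 0
    denom = 0
    for a, b in zip(s1, s2):
        if a == GAP and b == GAP:
            continue
        denom += 1
        if a == b:
            matches += 1
    return matches / denom if denom else 0.0


def _identity_matrix(X: np.ndarray) -> np.ndarray:
    """All-pairs fractional identity for an (N, L) index-coded alignment.

    Uses per-state one-hot Gram matrices so the cost is 21 dense matmuls
    rather than an N x N x L comparison tensor.
    """
    N, L = X.shape
    equal = np.zeros((N, N), dtype=np.float32)
    for a in np.unique(X):
        A = (X == a).astype(np.float32)
        equal += A @ A.T
    G = (X == _GAP_STATE).astype(np.float32)
    bothgap = G @ G.T
    denom = L - bothgap
    matches = equal - bothgap
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(denom > 0, matches / np.maximum(denom, 1.0), 0.0)
    return ident


def _cluster_labels(alignment: Alignment, threshold: float) -> np.ndarray:
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    X = alignment.to_indices()
    if X.shape[0] == 1:
        return np.zeros(1, dtype=int)
    # tolerance guards float32 Gram-matrix rounding at the exact threshold
    adj = _identity_matrix(X) >= threshold - 1e-6
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def cluster_sequences(alignment: Alignment, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> List[List[int]]:
    """Single-linkage clusters of sequence indices at an identity threshold.

    Two sequences share a cluster iff they are connected by a chain of pairs
    each with identity >= threshold (transitive closure of the identity
    graph).  Returns a partition of {0..N-1} ordered by first member.
    """
    labels = _cluster_labels(alignment, threshold)
    clusters: dict = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    return sorted(clusters.values(), key=lambda c: c[0])


def effective_sequences(alignment: Alignment, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> int:
    """N_eff: the number of 62%-identity single-linkage clusters."""
    return int(_cluster_labels(alignment, threshold).max()) + 1


def sequence_weights(alignment: Alignment, threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> np.ndarray:
    """Per-sequence weights 1/(cluster size); they sum to the cluster count."""
    labels = _cluster_labels(alignment, threshold)
    sizes = np.bincount(labels)
    return 1.0 / sizes[labels]


@dataclass
class WeightedAlignment:
    """An alignment bundled with redundancy weights and N_eff."""

    alignment: Alignment
    weights: np.ndarray
    neff: int
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.alignment.N,):
            raise ValueError("one weight per sequence required")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")
        if not (1 <= self.neff <= self.alignment.N):
            raise ValueError("neff must lie in [1, N]")

    @property
    def weighted_n(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_alignment(
        cls, alignment: Alignment, threshold: float = DEFAULT_IDENTITY_THRESHOLD
    ) -> "WeightedAlignment":
        labels = _cluster_labels(alignment, threshold)
        sizes = np.bincount(labels)
        weights = 1.0 / sizes[labels]
        return cls(
            alignment=alignment,
            weights=weights,
            neff=int(labels.max()) + 1,
            identity_threshold=threshold,
        )
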