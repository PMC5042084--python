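"""Potts model container and gauge utilities.

A Potts model over sequences x in {0..q-1}^L assigns energy

    E(x) = - sum_i h_i(x_i) - sum_{i<j} J_ij(x_i, x_j)

with single-site fields h and pairwise couplings J.  It is the maximum-
entropy model matching single- and pair-site statistics, the generative
counterpart that mean-field DCA and pseudolikelihood inference invert.

Couplings are stored as a dense (L, L, q, q) array with the symmetry
J[i, j, a, b] == J[j, i, b, a]; only i != j entries are meaningful.  The
zero-sum (Ising) gauge — every row and column of every coupling block sums
to zero — removes the reparameterization degeneracy and is the gauge in
which Frobenius-norm coupling scores are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import Q


def zero_sum_gauge_block(block: np.ndarray) -> np.ndarray:
    """Project one q x q coupling block onto the zero-sum gauge."""
    row = block.mean(axis=1, keepdims=True)
    col = block.mean(axis=0, keepdims=True)
    return block - row - col + block.mean()


@dataclass
class PottsModel:
    """Fields and couplings of a pairwise maximum-entropy sequence model."""

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q), J[i,j,a,b] = J[j,i,b,a]
    gauge: str = "none"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def to_zero_sum_gauge(self) -> "PottsModel":
        """Return an equivalent model with all coupling blocks zero-sum.

        The shifts absorbed from J are folded into the fields, so the
        probability distribution is unchanged.
        """
        L, q = self.L, self.q
        h = self.h.copy()
        J = np.zeros_like(self.J)
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                block = self.J[i, j]
                row = block.mean(axis=1)  # depends on a at site i
                J[i, j] = zero_sum_gauge_block(block)
                h[i] += row - row.mean()
        h -= h.mean(axis=1, keepdims=True)
        return PottsModel(h=h, J=J, gauge="zero-sum")

    def coupling_norms(self) -> np.ndarray:
        """L x L matrix of Frobenius norms of zero-sum-gauged blocks."""
        L = self.L
        out = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1, L):
                g = zero_sum_gauge_block(self.J[i, j])
                out[i, j] = out[j, i] = np.linalg.norm(g)
        return out

    def sequence_energy(self, x: np.ndarray) -> float:
        """Energy of one integer-coded sequence (lower = more probable)."""
        x = np.asarray(x)
        e = -self.h[np.arange(self.L), x].sum()
        for i in range(self.L):
            for j in range(i + 1, self.L):
                e -= self.J[i, j, x[i], x[j]]
        return float(e)


def make_symmetric_couplings(L: int, q: int = Q) -> np.ndarray:
    """Zero-initialized coupling tensor of the right shape."""
    return np.zeros((L, L, q, q))
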