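"""Per-pair feature assembly for the stage-1 network.

For every eligible residue pair (i, j) the feature vector combines:

* the APC-corrected coupling score of each included covariation method at
  (i, j);
* windowed column profiles: for each column in a window around i and around
  j, the 21 weighted state frequencies plus the column gap fraction and
  Shannon entropy (nats);
* a one-hot binned sequence separation;
* global alignment-depth terms ln(1 + N_eff) and ln(1 + N).

Optionally, per-residue 3-state secondary-structure probabilities and a
solvent-accessibility fraction can be appended per windowed column; these
are accepted as an input table, never predicted here.

Depth modulation between classical and covariation information is learned by
the network from the depth features rather than hand-coded: on shallow
alignments the covariation scores are noise and the profile/depth terms
carry the signal, and vice versa.

Feature vectors are symmetric in (i, j): pairs are canonicalized to i < j
and the two windows are always ordered (around min, around max).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .covariation import DEFAULT_MIN_SEPARATION, ScoreMatrix, compute_frequencies
from .weighting import WeightedAlignment

def shallow_gate_value(neff: float) -> float:
    """~1 for very shallow alignments, -> 0 as N_eff grows past ~50."""
    return 1.0 / (1.0 + neff / 50.0)


def depth_feature_vector(walign: WeightedAlignment) -> np.ndarray:
    """Global depth features: ln(1+N_eff), ln(1+N), shallow gate."""
    return np.array(
        [
            np.log1p(walign.neff),
            np.log1p(walign.alignment.N),
            shallow_gate_value(walign.neff),
        ]
    )


#: one-hot sequence-separation bins (inclusive bounds; last is open-ended)
SEPARATION_BINS: Tuple[Tuple[int, float], ...] = (
    (4, 8), (9, 13), (14, 18), (19, 23), (24, 38), (39, np.inf),
)


@dataclass
class FeatureConfig:
    column_window: int = 5  # columns around each of i and j (odd)
    include_methods: Tuple[str, ...] = ("MI", "MIp", "mfDCA", "PSICOV", "PLM")
    use_ss: bool = False
    use_acc: bool = False
    pad_value: float = -1.0
    min_separation: int = DEFAULT_MIN_SEPARATION

    def __post_init__(self) -> None:
        if self.column_window % 2 != 1:
            raise ValueError("column_window must be odd")
        if not self.include_methods:
            raise ValueError("at least one covariation method required")

    def n_features(self) -> int:
        per_col = 21 + 2  # profile + gap fraction + entropy
        if self.use_ss:
            per_col += 3
        if self.use_acc:
            per_col += 1
        # three features per method: raw score, within-family quantile rank,
        # and the shallow-gated rank interaction
        return (
            3 * len(self.include_methods)
            + 2 * self.column_window * per_col
            + len(SEPARATION_BINS)
            + 2
        )


@dataclass
class PairFeatures:
    """Feature matrix over eligible pairs, with bookkeeping."""

    pairs: List[Tuple[int, int]]  # 0-based, i < j
    matrix: np.ndarray  # (n_pairs, n_features)
    feature_names: List[str]
    L: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.pairs), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite feature values")


def read_aux_table(path, L: int) -> np.ndarray:
    """Read a per-residue auxiliary table `index aa ss_H ss_E ss_C acc`.

    Indices are 1-based; returns an (L, 4) array of [H, E, C, acc].
    """
    table = np.full((L, 4), np.nan)
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        idx = int(parts[0]) - 1
        if not 0 <= idx < L:
            raise ValueError(f"auxiliary-table index {idx + 1} out of range 1..{L}")
        table[idx] = [float(x) for x in parts[2:6]]
    if np.isnan(table).any():
        raise ValueError("auxiliary table does not cover all residues")
    return table


def separation_onehot(sep: int) -> np.ndarray:
    out = np.zeros(len(SEPARATION_BINS))
    for k, (lo, hi) in enumerate(SEPARATION_BINS):
        if lo <= sep <= hi:
            out[k] = 1.0
            break
    return out


def _column_profile_block(
    f1: np.ndarray,
    entropy: np.ndarray,
    aux: Optional[np.ndarray],
    center: int,
    window: int,
    pad_value: float,
    use_ss: bool,
    use_acc: bool,
) -> np.ndarray:
    L = f1.shape[0]
    half = window // 2
    per_col = 21 + 2 + (3 if use_ss else 0) + (1 if use_acc else 0)
    out = np.full(window * per_col, pad_value)
    for w, col in enumerate(range(center - half, center + half + 1)):
        if not 0 <= col < L:
            continue
        chunk = [f1[col], [f1[col, -1], entropy[col]]]
        if use_ss:
            chunk.append(aux[col, :3])
        if use_acc:
            chunk.append(aux[col, 3:4])
        out[w * per_col : (w + 1) * per_col] = np.concatenate(chunk)
    return out


def assemble_pair_features(
    walign: WeightedAlignment,
    scores: Sequence[ScoreMatrix],
    aux: Optional[np.ndarray] = None,
    config: Optional[FeatureConfig] = None,
) -> PairFeatures:
    """Build the stage-1 feature matrix for all pairs with |i-j| >= min_separation."""
    config = config or FeatureConfig()
    L = walign.alignment.L
    by_method = {s.method: s for s in scores}
    for m in config.include_methods:
        if m not in by_method:
            raise ValueError(f"score matrix for method {m!r} not provided")
        if by_method[m].L != L:
            raise ValueError(f"score matrix {m!r} has L={by_method[m].L}, expected {L}")
    if (config.use_ss or config.use_acc) and aux is None:
        raise ValueError("auxiliary SS/ACC table required by config but not given")

    freq = compute_frequencies(walign, pseudocount=0.0)
    f1 = freq.f1
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(f1 > 0, f1 * np.log(f1), 0.0).sum(axis=1)

    depth = np.array(
        [np.log1p(walign.neff), np.log1p(walign.alignment.N)]
    )

    # within-family quantile rank of each method's score: scale-free, so
    # the network can combine method *rankings* across alignment depths
    # where raw score magnitudes vary by orders of magnitude
    quantiles = {}
    for m in config.include_methods:
        sm = by_method[m]
        vals = sm.scores[sm.mask() & np.isfinite(sm.scores)]
        order = np.sort(vals)
        q = np.full_like(sm.scores, np.nan)
        finite = np.isfinite(sm.scores)
        q[finite] = np.searchsorted(order, sm.scores[finite], side="right") / max(
            len(order), 1
        )
        quantiles[m] = q

    # the gated rank features make depth-conditional method selection
    # linearly learnable (which engine to trust depends strongly on depth)
    shallow_gate = shallow_gate_value(walign.neff)

    names: List[str] = [f"score_{m}" for m in config.include_methods]
    names += [f"rank_{m}" for m in config.include_methods]
    names += [f"shallow_rank_{m}" for m in config.include_methods]
    per_col_names = [f"p_{a}" for a in range(21)] + ["gap_frac", "entropy"]
    if config.use_ss:
        per_col_names += ["ss_H", "ss_E", "ss_C"]
    if config.use_acc:
        per_col_names += ["acc"]
    half = config.column_window // 2
    for side in ("i", "j"):
        for off in range(-half, half + 1):
            names += [f"{side}{off:+d}_{n}" for n in per_col_names]
    names += [f"sep_{lo}_{hi}" for lo, hi in SEPARATION_BINS]
    names += ["log1p_neff", "log1p_n"]

    pairs: List[Tuple[int, int]] = []
    rows: List[np.ndarray] = []
    # column blocks reused across pairs
    blocks = [
        _column_profile_block(
            f1, ent, aux, c, config.column_window, config.pad_value,
            config.use_ss, config.use_acc,
        )
        for c in range(L)
    ]
    for i in range(L):
        for j in range(i + config.min_separation, L):
            method_scores = np.array(
                [by_method[m].scores[i, j] for m in config.include_methods]
            )
            method_ranks = np.array(
                [quantiles[m][i, j] for m in config.include_methods]
            )
            vec = np.concatenate(
                [method_scores, method_ranks, shallow_gate * method_ranks,
                 blocks[i], blocks[j], separation_onehot(j - i), depth]
            )
            pairs.append((i, j))
            rows.append(vec)
    matrix = np.vstack(rows) if rows else np.empty((0, len(names)))
    return PairFeatures(pairs=pairs, matrix=matrix, feature_names=names, L=L)
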