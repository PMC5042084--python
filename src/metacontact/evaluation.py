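"""CASP-style contact evaluation: ranked lists, top-L/k precision, RR I/O.

Long-range (LR) contacts are pairs with sequence separation |i-j| > 23;
short-range (SR) pairs have 4 <= |i-j| <= 23, so the two classes partition
the eligible range (separation exactly 23 goes to SR).  The headline metric
is top-L/5 LR precision: predictions are restricted to the class, the
floor(L/5) highest-probability pairs (minimum 1) are selected, and precision
is the percentage of those that are true contacts.

The RR format is the CASP plain-text contact submission format: lines
``i j 0 8 p`` with 1-based indices i < j, bracketed by ``PFRMAT RR`` /
``MODEL`` / ``END`` records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Set, Tuple

import numpy as np

DEFAULT_K_FRACTION = 0.2
LR_MIN_SEPARATION = 24  # "long range" means separation > 23
SR_RANGE = (4, 23)


@dataclass
class ContactList:
    """Ranked contact predictions, 1-based pairs i < j."""

    entries: List[Tuple[int, int, float]]
    L: int

    def __post_init__(self) -> None:
        seen = set()
        for i, j, p in self.entries:
            if not (1 <= i < j <= self.L):
                raise ValueError(f"invalid pair ({i}, {j}) for L={self.L}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i}, {j})")
            seen.add((i, j))
        self.entries = sorted(self.entries, key=lambda t: (-t[2], t[0], t[1]))

    @classmethod
    def from_probability_map(cls, cmap, L: int | None = None) -> "ContactList":
        """Build from a ContactProbabilityMap (0-based) -> 1-based entries."""
        entries = [(i + 1, j + 1, p) for i, j, p in cmap.ranked_pairs()]
        return cls(entries=entries, L=L or cmap.L)

    @classmethod
    def from_score_matrix(cls, sm) -> "ContactList":
        """Build from a ScoreMatrix, mapping ranks to pseudo-probabilities.

        Raw coupling scores are not probabilities; entries are assigned
        evenly spaced pseudo-probabilities by rank so list order (the only
        thing precision uses) is preserved.
        """
        ranked = sm.ranked_pairs()
        n = len(ranked)
        entries = [
            (i + 1, j + 1, (n - r) / n) for r, (i, j, _) in enumerate(ranked)
        ]
        return cls(entries=entries, L=sm.L)


@dataclass
class EvalConfig:
    k_fraction: float = DEFAULT_K_FRACTION
    lr_min_separation: int = LR_MIN_SEPARATION
    sr_range: Tuple[int, int] = SR_RANGE

    def __post_init__(self) -> None:
        if not (0.0 < self.k_fraction <= 1.0):
            raise ValueError("k_fraction must be in (0, 1]")
        if self.lr_min_separation <= 4:
            raise ValueError("lr_min_separation must exceed 4")


def _in_class(sep: int, cls: str, config: EvalConfig) -> bool:
    if cls == "LR":
        return sep >= config.lr_min_separation
    if cls == "SR":
        return config.sr_range[0] <= sep <= config.sr_range[1]
    if cls == "all":
        return sep >= config.sr_range[0]
    raise ValueError(f"unknown separation class {cls!r}")


def topk_precision(
    pred: ContactList,
    truth: Set[Tuple[int, int]],
    config: EvalConfig | None = None,
    cls: str = "LR",
) -> float:
    """Top-floor(L*k) precision (percent) within a separation class.

    ``truth`` holds 1-based (i, j) pairs with i < j.  If fewer than the
    nominal top-k predictions survive the class filter, all survivors are
    used (the denominator is the number actually selected).
    """
    config = config or EvalConfig()
    for i, j in truth:
        if not (1 <= i < j <= pred.L):
            raise ValueError(f"truth pair ({i}, {j}) invalid for L={pred.L}")
    filtered = [e for e in pred.entries if _in_class(e[1] - e[0], cls, config)]
    if not filtered:
        raise ValueError(f"no predictions in separation class {cls}")
    k = max(1, int(pred.L * config.k_fraction))
    selected = filtered[:k]
    tp = sum(1 for i, j, _ in selected if (i, j) in truth)
    return 100.0 * tp / len(selected)


# ---------------------------------------------------------------------------
# CASP RR format
# ---------------------------------------------------------------------------

def write_rr(pred: ContactList, path, target: str = "T0000") -> None:
    """Write a CASP RR file: `i j 0 8 p` lines with p to 3 decimals."""
    lines = ["PFRMAT RR", f"TARGET {target}", "MODEL 1"]
    lines += [f"{i} {j} 0 8 {p:.3f}" for i, j, p in pred.entries]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rr(path, L: int | None = None) -> ContactList:
    """Read a CASP RR file back into a ContactList.

    ``L`` defaults to the largest residue index seen.
    """
    entries: List[Tuple[int, int, float]] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts or parts[0] in ("PFRMAT", "TARGET", "MODEL", "END", "REMARK"):
            continue
        if len(parts) != 5:
            raise ValueError(f"malformed RR line: {line!r}")
        i, j = int(parts[0]), int(parts[1])
        p = float(parts[4])
        if j <= i:
            raise ValueError(f"RR pairs must satisfy i < j: {line!r}")
        entries.append((i, j, p))
    if not entries:
        raise ValueError(f"no contact records in {path}")
    Lmax = max(j for _, j, _ in entries)
    return ContactList(entries=entries, L=L or Lmax)


# ---------------------------------------------------------------------------
# precision-vs-depth benchmark harness
# ---------------------------------------------------------------------------

def contact_ranking_auc(sm_or_map, truth0: Set[Tuple[int, int]]) -> float:
    """AUC of true contacts vs non-contacts over eligible pairs (0-based truth)."""
    ranked = sm_or_map.ranked_pairs()
    labels = np.array([1 if (i, j) in truth0 else 0 for i, j, _ in ranked])
    scores = np.arange(len(ranked), 0, -1)  # rank order carries the information
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both contacts and non-contacts")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def benchmark_by_neff(
    families: Sequence[Tuple[int, "ContactList", Set[Tuple[int, int]]]],
    config: EvalConfig | None = None,
    cls: str = "LR",
):
    """Aggregate top-L/5 precision by N_eff stratum.

    ``families`` holds (neff_stratum, predictions, 1-based truth) tuples.
    Returns a pandas DataFrame with one row per stratum: (neff_stratum,
    mean_precision, n_families), sorted by stratum.
    """
    import pandas as pd

    config = config or EvalConfig()
    if not families:
        raise ValueError("no families supplied")
    rows = []
    for stratum, pred, truth in families:
        rows.append(
            {"neff_stratum": stratum, "precision": topk_precision(pred, truth, config, cls)}
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby("neff_stratum")["precision"]
        .agg(mean_precision="mean", n_families="count")
        .reset_index()
        .sort_values("neff_stratum", ignore_index=True)
    )
    if (out["n_families"] == 0).any():
        raise ValueError("empty stratum")
    return out
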