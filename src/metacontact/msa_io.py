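"""Multiple sequence alignment I/O and the alignment-pipeline decision rules.

Alignments are read from FASTA, A3M (lowercase columns are insertions
relative to the query and are removed) or PSICOV-style flat files (one raw
aligned sequence per line, query first).  All sequences are canonicalized to
the 21-letter alphabet: the 20 standard amino acids plus the gap character
``-``.  Ambiguity and non-standard codes (B, Z, X, U, O, J) carry no usable
covariation signal at the single-residue level and are mapped to the gap
state so the state space stays at 21, as in standard DCA practice.

The module also records the decision logic of the hybrid alignment-generation
pipeline (HHblits against UniRef20, supplemented by a jackHMMer-built custom
database when the first alignment is shallow).  The external tools themselves
are never executed here; only the machine-checkable parameters and the two
pure decision functions (:func:`needs_supplement`,
:func:`select_deeper_alignment`) are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # index 20 is the gap/unknown state
Q = len(ALPHABET)

#: Codes with no single-residue covariation information; treated as gap.
_AMBIGUOUS = set("BZXUOJ")
_GAPLIKE = set("-.~")

STATE_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class MSAFormatError(ValueError):
    """Raised for unparseable or invalid alignment input."""


def canonicalize_char(c: str) -> str:
    """Map one raw alignment character onto the 21-letter alphabet."""
    c = c.upper()
    if c in _GAPLIKE:
        return GAP
    if c in _AMBIGUOUS:
        return GAP
    if c in STATE_INDEX:
        return c
    raise MSAFormatError(f"illegal alignment character {c!r}")


@dataclass
class Alignment:
    """An MSA over the 20 amino acids + gap, query row first.

    Parameters
    ----------
    ids:
        Sequence identifiers; duplicates are permitted and kept.
    rows:
        Aligned, canonicalized sequences, all of length ``L``.
    query_index:
        Row index of the query (always 0 for parsed files).
    """

    ids: List[str]
    rows: List[str]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise MSAFormatError("alignment has no sequences")
        L = len(self.rows[0])
        if L < 1:
            raise MSAFormatError("alignment has zero columns")
        for r in self.rows:
            if len(r) != L:
                raise MSAFormatError(
                    f"ragged alignment: row length {len(r)} != {L}"
                )
            for c in r:
                if c not in STATE_INDEX:
                    raise MSAFormatError(f"illegal alignment character {c!r}")
        if len(self.ids) != len(self.rows):
            raise MSAFormatError("ids and rows differ in length")

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    def to_indices(self):
        """Integer-encode the alignment as an (N, L) uint8 array."""
        import numpy as np

        out = np.empty((self.N, self.L), dtype=np.uint8)
        for s, row in enumerate(self.rows):
            for i, c in enumerate(row):
                out[s, i] = STATE_INDEX[c]
        return out


@dataclass
class PipelineConfig:
    """Recorded parameters of the hybrid alignment-generation pipeline."""

    hhblits_evalue: float = 1e-3
    hhblits_coverage_pct: float = 50.0
    hhblits_iterations: int = 3
    jackhmmer_evalue: float = 10.0
    jackhmmer_iterations: int = 3
    depth_threshold: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "hhblits_evalue",
            "hhblits_coverage_pct",
            "hhblits_iterations",
            "jackhmmer_evalue",
            "jackhmmer_iterations",
            "depth_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _canonicalize_a3m_row(raw: str) -> str:
    # lowercase = insertion relative to the query; drop, then canonicalize
    return "".join(canonicalize_char(c) for c in raw if not c.islower())


def _canonicalize_row(raw: str) -> str:
    return "".join(canonicalize_char(c) for c in raw)


def _parse_fasta_records(text: str) -> Iterable[tuple]:
    header = None
    chunks: List[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        else:
            if header is None:
                raise MSAFormatError("sequence data before first FASTA header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def parse_msa(path, format: str = "fasta") -> Alignment:
    """Read an alignment file.

    ``format`` is one of ``fasta``, ``a3m`` or ``flat``.  For A3M, lowercase
    characters (insertions relative to the query) are deleted so every row
    matches the query length; the query row itself is never altered by this
    rule because query insertions do not exist by construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise MSAFormatError(f"empty alignment file: {path}")

    ids: List[str] = []
    rows: List[str] = []
    if format in ("fasta", "a3m"):
        canon = _canonicalize_a3m_row if format == "a3m" else _canonicalize_row
        for header, seq in _parse_fasta_records(text):
            ids.append(header)
            rows.append(canon(seq))
        if not rows:
            raise MSAFormatError(f"no FASTA records in {path}")
    elif format == "flat":
        for k, line in enumerate(l for l in text.splitlines() if l.strip()):
            ids.append(f"seq{k}")
            rows.append(_canonicalize_row(line.strip()))
    else:
        raise ValueError(f"unsupported format {format!r}")
    return Alignment(ids=ids, rows=rows)


def write_msa(alignment: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment in FASTA or flat format."""
    path = Path(path)
    if format == "fasta":
        lines = []
        for i, (h, r) in enumerate(zip(alignment.ids, alignment.rows)):
            lines.append(f">{h or f'seq{i}'}")
            lines.append(r)
        path.write_text("\n".join(lines) + "\n")
    elif format == "flat":
        path.write_text("\n".join(alignment.rows) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def needs_supplement(alignment: Alignment, config: PipelineConfig) -> bool:
    """True iff the first-pass alignment is shallow (< depth_threshold rows).

    This is the branch condition of the hybrid pipeline: a shallow HHblits
    alignment triggers the jackHMMer custom-database supplement run.
    """
    return alignment.N < config.depth_threshold


def select_deeper_alignment(a: Alignment, b: Alignment) -> Alignment:
    """Return whichever alignment has more sequences.

    Both alignments must share the same (gap-stripped) query sequence.  Ties
    go to ``a``, the first-pass alignment.
    """
    qa = a.query.replace(GAP, "")
    qb = b.query.replace(GAP, "")
    if qa != qb:
        raise ValueError("alignments have different query sequences")
    return b if b.N > a.N else a
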