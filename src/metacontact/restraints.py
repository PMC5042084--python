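"""Contact-map energy restraints and 3D structure scoring.

Predicted contacts enter a folding engine as attractive pair potentials.
Each pair with predicted probability >= 0.5 (the PPV cutoff) contributes a
square well of depth equal to its probability for Cbeta-Cbeta distances up
to 8 A, decaying smoothly to zero beyond.  Short-range (4 <= |i-j| <= 23)
and long-range (|i-j| >= 24) restraints are summed into separate energy
terms, because otherwise the abundant and easily predicted short-range
contacts swamp the long-range signal that actually determines the fold.

The decay above the well is Gaussian in the excess distance with a
configurable width (default 2 A); a single-exponential form is available
behind the same configuration since the exact fall-off constant is a
folding-engine choice, not a property of the contact predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

SR_MAX_SEPARATION = 23  # separation <= 23 is short-range; >= 24 long-range


@dataclass
class RestraintConfig:
    p_min: float = 0.5
    d0: float = 8.0  # contact distance threshold, Angstroms
    decay_sigma: float = 2.0  # decay width, Angstroms
    sr_max_separation: int = SR_MAX_SEPARATION
    decay_form: str = "gaussian"  # or "exponential"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_min <= 1.0):
            raise ValueError("p_min must be in (0, 1]")
        if self.d0 <= 0 or self.decay_sigma <= 0:
            raise ValueError("d0 and decay_sigma must be positive")
        if self.decay_form not in ("gaussian", "exponential"):
            raise ValueError("decay_form must be 'gaussian' or 'exponential'")


@dataclass
class Restraint:
    i: int  # 1-based residue indices, i < j
    j: int
    weight: float  # = predicted contact probability
    cls: str  # "SR" or "LR"


@dataclass
class RestraintEnergy:
    e_sr: float
    e_lr: float
    contributions: List[Tuple[int, int, str, float]]  # (i, j, class, energy)

    @property
    def total(self) -> float:
        return self.e_sr + self.e_lr


def build_restraints(cmap, config: RestraintConfig | None = None) -> List[Restraint]:
    """Select map entries with probability >= p_min and classify SR/LR.

    Accepts a ContactProbabilityMap (0-based internal indices; emitted
    restraints are 1-based).
    """
    config = config or RestraintConfig()
    out: List[Restraint] = []
    for i, j, p in cmap.ranked_pairs():
        if p < config.p_min:
            continue
        sep = j - i
        cls = "SR" if sep <= config.sr_max_separation else "LR"
        out.append(Restraint(i=i + 1, j=j + 1, weight=p, cls=cls))
    return out


def restraints_from_contact_list(
    pred, config: RestraintConfig | None = None
) -> List[Restraint]:
    """Build restraints straight from a (1-based) ContactList."""
    config = config or RestraintConfig()
    out: List[Restraint] = []
    for i, j, p in pred.entries:
        if p < config.p_min or j - i < 4:
            continue
        cls = "SR" if j - i <= config.sr_max_separation else "LR"
        out.append(Restraint(i=i, j=j, weight=p, cls=cls))
    return out


def pair_energy(distance: float, weight: float, config: RestraintConfig | None = None) -> float:
    """Square-well pair energy with smooth decay above the contact threshold.

    E = -weight for d <= d0;
    E = -weight * exp(-(d - d0)^2 / (2 sigma^2))   (gaussian decay), or
    E = -weight * exp(-(d - d0) / sigma)           (exponential decay)
    for d > d0.  Continuous at d0 in either form.
    """
    config = config or RestraintConfig()
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance <= config.d0:
        return -weight
    excess = distance - config.d0
    if config.decay_form == "gaussian":
        return -weight * float(np.exp(-(excess**2) / (2.0 * config.decay_sigma**2)))
    return -weight * float(np.exp(-excess / config.decay_sigma))


@dataclass
class StructureCoords:
    """Per-residue contact-atom coordinates (Cbeta; Calpha for glycine)."""

    coords: Dict[int, np.ndarray]  # 1-based residue index -> xyz

    def __post_init__(self) -> None:
        for idx, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(f"bad coordinates for residue {idx}")
            self.coords[idx] = xyz

    def distance(self, i: int, j: int) -> float:
        try:
            return float(np.linalg.norm(self.coords[i] - self.coords[j]))
        except KeyError as e:
            raise KeyError(f"residue {e.args[0]} missing from structure") from None

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "StructureCoords":
        """From an (L, 3) array; residue k (0-based) becomes index k+1."""
        return cls({k + 1: np.asarray(row, dtype=float) for k, row in enumerate(arr)})


def read_pdb_coords(path) -> StructureCoords:
    """Extract Cbeta (Calpha for glycine) coordinates from a PDB file.

    Uses the first model and the first chain's ATOM records, first alternate
    location only.  A residue with neither CB nor CA is an error.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", str(path))
    try:
        model = next(structure.get_models())
        chain = next(model.get_chains())
    except StopIteration:
        raise ValueError(f"no ATOM records found in {path}") from None
    coords: Dict[int, np.ndarray] = {}
    for k, residue in enumerate(r for r in chain if r.id[0] == " "):
        atom = None
        if residue.get_resname().strip() != "GLY" and "CB" in residue:
            atom = residue["CB"]
        elif "CA" in residue:
            atom = residue["CA"]
        if atom is None:
            raise ValueError(
                f"residue {residue.id[1]} has neither CB nor CA atom"
            )
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        coords[k + 1] = np.asarray(atom.get_coord(), dtype=float)
    if not coords:
        raise ValueError(f"no ATOM records found in {path}")
    return StructureCoords(coords=coords)


def score_structure(
    coords: StructureCoords,
    restraints: List[Restraint],
    config: RestraintConfig | None = None,
) -> RestraintEnergy:
    """Sum restraint energies into separate short- and long-range terms."""
    config = config or RestraintConfig()
    e = {"SR": 0.0, "LR": 0.0}
    contributions = []
    for r in restraints:
        d = coords.distance(r.i, r.j)
        ei = pair_energy(d, r.weight, config)
        e[r.cls] += ei
        contributions.append((r.i, r.j, r.cls, ei))
    return RestraintEnergy(e_sr=e["SR"], e_lr=e["LR"], contributions=contributions)
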