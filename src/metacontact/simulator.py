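"""Synthetic protein families with known contact topologies.

Every learnable and testable quantity in this package ultimately needs an
alignment whose true contact map is known.  This module provides one: a
compact self-avoiding chain supplies a contact topology, a Potts model is
built on that topology (couplings only between contacting residues), and a
Gibbs sampler draws sequences from the model.  Because the generative model
is exactly the maximum-entropy family that mfDCA / PSICOV / pseudolikelihood
inference inverts, recovery of the topology from the sampled alignment is a
well-posed parameter-recovery experiment.

Conventions (package choices, stated here once):

* Distance units are Angstroms by convention, so the 8 A Cbeta-Cbeta contact
  threshold is used verbatim.  Chain bond length is 3.8 A (Calpha-like),
  excluded volume radius 4.0 A.
* Chains are confined to a sphere whose volume allots ~160 A^3 per residue,
  giving compact globular-like conformations; without confinement a random
  self-avoiding walk of modest length almost never forms long-range
  (|i-j| > 23) contacts.
* Sampled sequences are gapless: the gap state is excluded from Gibbs
  proposals (real family members can of course contain gaps; redundancy
  padding introduces substitutions only).
* One global seed fans out to per-stage sub-seeds via
  ``numpy.random.SeedSequence(seed).spawn``, in the fixed order topology,
  potts, gibbs, padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Set, Tuple

import numpy as np

from .msa_io import Alignment, AMINO_ACIDS, Q
from .potts import PottsModel
from .weighting import effective_sequences

BOND_LENGTH = 3.8
EXCLUDED_VOLUME = 4.0
CONTACT_THRESHOLD = 8.0
RESIDUE_VOLUME = 160.0
CONTACT_MIN_SEPARATION = 4

# background amino-acid composition (approximate database frequencies)
_BACKGROUND = np.array(
    [8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()


@dataclass
class ContactTopology:
    """A coarse 3D chain and the contact set it induces."""

    coords: np.ndarray  # (L, 3)
    contacts: Set[Tuple[int, int]]  # 0-based (i, j), i < j, |i-j| >= 4

    @property
    def L(self) -> int:
        return self.coords.shape[0]

    def contact_map(self) -> np.ndarray:
        cm = np.zeros((self.L, self.L), dtype=bool)
        for i, j in self.contacts:
            cm[i, j] = cm[j, i] = True
        return cm


@dataclass
class SimConfig:
    """Study conditions for one synthetic family."""

    L: int = 30
    n_sequences: int = 2000
    coupling_strength: float = 1.2  # beta, scale of coupling blocks
    mutation_rate: float = 0.1  # per-site rate for redundancy padding
    target_neff: Optional[int] = None
    burn_in: int = 50  # Gibbs sweeps before harvesting
    thinning: int = 5  # sweeps between harvests
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.L, self.n_sequences, self.burn_in, self.thinning) < 1:
            raise ValueError("L, n_sequences, burn_in, thinning must be >= 1")
        if self.coupling_strength < 0 or not (0 <= self.mutation_rate <= 1):
            raise ValueError("invalid coupling_strength or mutation_rate")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def _subseeds(seed: int, n: int = 4) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def sample_topology(L: int, seed: int, max_restarts: int = 200) -> ContactTopology:
    """Grow a compact self-avoiding chain and read off its contacts.

    Bonds have fixed length, residues may not approach closer than the
    excluded-volume radius, and the chain must stay inside a confinement
    sphere sized to ~160 A^3 per residue.  Dead ends trigger a bounded
    restart with a fresh sub-seed.
    """
    if L < 5:
        raise ValueError("L must be >= 5")
    radius = (3.0 * RESIDUE_VOLUME * L / (4.0 * np.pi)) ** (1.0 / 3.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(max_restarts):
        coords = _grow_chain(L, radius, rng)
        if coords is not None:
            contacts = _contacts_from_coords(coords)
            return ContactTopology(coords=coords, contacts=contacts)
    raise RuntimeError(f"failed to grow a chain of length {L} in {max_restarts} restarts")


def _grow_chain(L: int, radius: float, rng: np.random.Generator) -> Optional[np.ndarray]:
    coords = np.zeros((L, 3))
    for i in range(1, L):
        placed = False
        for _ in range(60):
            v = rng.standard_normal(3)
            v *= BOND_LENGTH / np.linalg.norm(v)
            cand = coords[i - 1] + v
            if np.linalg.norm(cand) > radius:
                continue
            if i >= 2:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if (d < EXCLUDED_VOLUME).any():
                    continue
            coords[i] = cand
            placed = True
            break
        if not placed:
            return None
    return coords - coords.mean(axis=0)


def _contacts_from_coords(coords: np.ndarray) -> Set[Tuple[int, int]]:
    L = coords.shape[0]
    contacts = set()
    for i in range(L):
        d = np.linalg.norm(coords[i + CONTACT_MIN_SEPARATION:] - coords[i], axis=1)
        for k in np.nonzero(d <= CONTACT_THRESHOLD)[0]:
            contacts.add((i, i + CONTACT_MIN_SEPARATION + int(k)))
    return contacts


def build_potts(topology: ContactTopology, beta: float, seed: int) -> PottsModel:
    """Potts model whose couplings live exactly on the contact topology.

    Contact pairs receive random zero-sum-gauge coupling blocks scaled by
    ``beta``; all other blocks are exactly zero.  Fields follow a fixed
    background amino-acid composition; the gap state is effectively
    forbidden (strongly negative field).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L = topology.L
    h = np.tile(np.concatenate([np.log(_BACKGROUND), [-30.0]]), (L, 1))
    J = np.zeros((L, L, Q, Q))
    from .potts import zero_sum_gauge_block

    for i, j in sorted(topology.contacts):
        block = np.zeros((Q, Q))
        block[:20, :20] = zero_sum_gauge_block(rng.standard_normal((20, 20)))
        J[i, j] = beta * block
        J[j, i] = beta * block.T
    return PottsModel(h=h, J=J, gauge="zero-sum")


def gibbs_sample_msa(model: PottsModel, config: SimConfig) -> Alignment:
    """Draw an alignment from a Potts model by parallel single-site Gibbs.

    ``n_sequences`` chains run in parallel from independent random starts;
    after ``burn_in`` full sweeps, the state of every chain is harvested
    every ``thinning`` sweeps until one sequence per chain is collected
    (a single harvest).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    L, q = model.L, model.q
    n = config.n_sequences
    # amino-acid states only: gap field is -30, excluded from proposals
    X = rng.integers(0, 20, size=(n, L))
    h = model.h
    total_sweeps = config.burn_in + config.thinning
    for sweep in range(total_sweeps):
        for i in range(L):
            logits = np.tile(h[i, :20], (n, 1))
            for j in range(L):
                if j == i:
                    continue
                logits += model.J[i, j, :20, :][:, X[:, j]].T
            g = rng.gumbel(size=(n, 20))
            X[:, i] = np.argmax(logits + g, axis=1)
    rows = ["".join(AMINO_ACIDS[a] for a in row) for row in X]
    ids = [f"sim{k}" for k in range(n)]
    return Alignment(ids=ids, rows=rows)


def _pad_to_target_neff(
    alignment: Alignment,
    topology: ContactTopology,
    config: SimConfig,
    rng: np.random.Generator,
) -> Alignment:
    """Reach a target N_eff by keeping a diverse core and padding duplicates.

    The first ``target_neff`` sampled sequences act as cluster seeds; the
    remaining rows are near-duplicates of the seeds (per-site substitutions
    at ``mutation_rate``), which mimics the shallow, redundant families
    whose depth the N_eff statistic is designed to measure.
    """
    target = config.target_neff
    n_total = alignment.N
    if target is None:
        return alignment
    if target > n_total:
        raise ValueError("target_neff cannot exceed n_sequences")
    seeds = alignment.rows[:target]
    rows = list(seeds)
    ids = [f"core{k}" for k in range(target)]
    k = 0
    while len(rows) < n_total:
        src = seeds[k % target]
        arr = np.frombuffer(src.encode(), dtype=np.uint8).copy()
        mut = rng.random(len(arr)) < config.mutation_rate
        arr[mut] = np.frombuffer(
            "".join(AMINO_ACIDS[a] for a in rng.integers(0, 20, size=int(mut.sum()))).encode(),
            dtype=np.uint8,
        )
        rows.append(arr.tobytes().decode())
        ids.append(f"pad{k}")
        k += 1
    padded = Alignment(ids=ids, rows=rows)
    neff = effective_sequences(padded)
    if abs(neff - target) > max(1, 0.1 * target):
        raise RuntimeError(
            f"redundancy padding reached N_eff={neff}, target was {target}"
        )
    return padded


def generate_family(config: SimConfig) -> Tuple[Alignment, ContactTopology]:
    """Topology -> Potts -> Gibbs pipeline, with optional N_eff control."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    topo_seed = int(ss[0].generate_state(1)[0] % (2**31))
    potts_seed = int(ss[1].generate_state(1)[0] % (2**31))
    topology = sample_topology(config.L, topo_seed)
    model = build_potts(topology, config.coupling_strength, potts_seed)
    alignment = gibbs_sample_msa(model, config)
    if config.target_neff is not None:
        rng = np.random.default_rng(ss[3])
        alignment = _pad_to_target_neff(alignment, topology, config, rng)
    return alignment, topology


def write_truth(topology: ContactTopology, path) -> None:
    """Write the true contact set as 1-based `i<TAB>j` lines, i < j."""
    lines = [f"{i + 1}\t{j + 1}" for i, j in sorted(topology.contacts)]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path) -> Set[Tuple[int, int]]:
    """Read a truth file back into a 0-based contact set."""
    from pathlib import Path

    contacts = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        i, j = (int(t) for t in line.split())
        if not i < j:
            raise ValueError(f"truth pairs must satisfy i < j: {line!r}")
        contacts.add((i - 1, j - 1))
    return contacts
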