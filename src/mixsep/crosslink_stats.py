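"""Crosslinking statistic L_i-j: observed vs random-mixing contact shares.

For species i and j within the condensate,

    f_contact(i, j) = N[i][j] / sum_k N[i][k]            (observed share)
    f_expected(i, j) = N_mol[j] / (sum_k N_mol[k] - 1)    for i != j
                     = (N_mol[j] - 1) / (sum_k N_mol[k] - 1)  for i == j
    L[i][j] = f_contact(i, j) / f_expected(i, j)

where N[i][j] are intermolecular bead-bead contact counts accumulated from
the perspective of species-i molecules (each same-species contact has two
species-i endpoints, so the diagonal counts both; the matrix stays
symmetric) and N_mol[j] counts condensate molecules per species.  The
"minus one" in f_expected excludes the molecule from whose perspective the
share is computed, leaving only intermolecular partners.  Under random
mixing every L equals 1; L > 1 marks enrichment of i-j crosslinks and
L < 1 depletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .condensate_geometry import find_condensate
from .lattice_engine import LatticeState, Trajectory, _OFFS

__all__ = [
    "ContactCounts",
    "CrosslinkMatrix",
    "count_contacts",
    "f_contact",
    "f_expected",
    "crosslink_L",
    "temperature_sweep",
]


@dataclass
class ContactCounts:
    """Intermolecular contact counts and molecule counts per species.

    ``n_contact[i][j]`` counts species-i bead endpoints of intermolecular
    contacts with species-j molecules: an i-j contact with i != j adds one
    to both [i][j] and [j][i]; an i-i contact adds two to the diagonal
    (both endpoints belong to species i).  This endpoint convention is what
    makes L exactly 1 under random mixing.
    """

    species: tuple[str, ...]
    n_contact: np.ndarray  # (S, S) symmetric integers
    n_mol: np.ndarray  # (S,) molecules in the condensate

    def __post_init__(self) -> None:
        self.n_contact = np.asarray(self.n_contact, dtype=np.int64)
        self.n_mol = np.asarray(self.n_mol, dtype=np.int64)
        s = len(self.species)
        if self.n_contact.shape != (s, s):
            raise ValueError("contact matrix shape must match species list")
        if (self.n_contact < 0).any() or (self.n_mol < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.n_contact != self.n_contact.T).any():
            raise ValueError("contact counts must be symmetric")

    def index(self, name: str) -> int:
        return self.species.index(name)


def count_contacts(
    state: LatticeState,
    condensate_chains: Iterable[int],
    anisotropic_only: bool = False,
) -> ContactCounts:
    """Accumulate intermolecular contacts within the condensate.

    A contact is any nonbonded 26-neighborhood bead pair whose two beads
    belong to different chains, both inside the condensate; intra-chain
    pairs never count.  ``anisotropic_only`` restricts counting to
    anisotropic partnerships instead.  Same-species contacts enter the
    diagonal twice (endpoint convention, see :class:`ContactCounts`).
    """
    sys_ = state.system
    L = sys_.L
    chains = set(int(c) for c in condensate_chains)
    names = sys_.species_names
    s = len(names)
    n_contact = np.zeros((s, s), dtype=np.int64)
    chain_of_bead = sys_.chain_of_bead
    species_of_chain = sys_.species_of_chain
    in_cond = np.zeros(sys_.n_chains, dtype=bool)
    in_cond[list(chains)] = True
    if anisotropic_only:
        for b, pb in enumerate(state.partner):
            if pb > b:
                cb, cp = chain_of_bead[b], chain_of_bead[pb]
                if cb == cp or not (in_cond[cb] and in_cond[cp]):
                    continue
                si, sj = species_of_chain[cb], species_of_chain[cp]
                n_contact[si, sj] += 1
                n_contact[sj, si] += 1
    else:
        occ = state.occ
        pos = state.positions
        for b in range(sys_.n_beads):
            cb = chain_of_bead[b]
            if not in_cond[cb]:
                continue
            x, y, z = pos[b]
            for k in range(26):
                q = occ[(x + _OFFS[k, 0]) % L, (y + _OFFS[k, 1]) % L,
                        (z + _OFFS[k, 2]) % L]
                if q <= b:
                    continue  # count each unordered pair once
                cq = chain_of_bead[q]
                if cq == cb or not in_cond[cq]:
                    continue
                si, sj = species_of_chain[cb], species_of_chain[cq]
                n_contact[si, sj] += 1
                n_contact[sj, si] += 1
    n_mol = np.zeros(s, dtype=np.int64)
    for c in chains:
        n_mol[species_of_chain[c]] += 1
    return ContactCounts(species=names, n_contact=n_contact, n_mol=n_mol)


def f_contact(counts: ContactCounts, i: int | str, j: int | str) -> float:
    """Observed share of species-i contacts made with species j."""
    i = counts.index(i) if isinstance(i, str) else i
    j = counts.index(j) if isinstance(j, str) else j
    denom = counts.n_contact[i].sum()
    if denom == 0:
        raise ValueError(
            f"species {counts.species[i]!r} has no intermolecular contacts"
        )
    return float(counts.n_contact[i, j] / denom)


def f_expected(counts: ContactCounts, i: int | str, j: int | str) -> float:
    """Random-mixing share of species-j partners from an i molecule's view.

    The molecule itself is excluded (hence the minus one), leaving only
    intermolecular partners.
    """
    i = counts.index(i) if isinstance(i, str) else i
    j = counts.index(j) if isinstance(j, str) else j
    total = counts.n_mol.sum()
    if total < 2:
        raise ValueError("random-mixing share undefined for <2 molecules")
    if i == j:
        return float((counts.n_mol[j] - 1) / (total - 1))
    return float(counts.n_mol[j] / (total - 1))


@dataclass
class CrosslinkMatrix:
    """L[i][j] per ordered species pair, NaN where undefined."""

    species: tuple[str, ...]
    L: np.ndarray
    temperature: float | None = None
    stderr: np.ndarray | None = None
    n_replicates: int = 1

    def value(self, i: str, j: str) -> float:
        return float(self.L[self.species.index(i), self.species.index(j)])

    def to_frame(self):
        import pandas as pd

        rows = []
        for a, ni in enumerate(self.species):
            for b, nj in enumerate(self.species):
                rows.append(
                    {
                        "temperature": self.temperature,
                        "i": ni,
                        "j": nj,
                        "L": self.L[a, b],
                        "stderr": (
                            self.stderr[a, b] if self.stderr is not None
                            else np.nan
                        ),
                        "n_replicates": self.n_replicates,
                    }
                )
        return pd.DataFrame(rows)


def crosslink_L(counts: ContactCounts) -> CrosslinkMatrix:
    """L[i][j] = f_contact(i, j) / f_expected(i, j), NaN where undefined."""
    s = len(counts.species)
    L = np.full((s, s), np.nan)
    total = counts.n_mol.sum()
    for i in range(s):
        if counts.n_contact[i].sum() == 0 or total < 2:
            continue
        for j in range(s):
            fe = f_expected(counts, i, j)
            if fe == 0:
                continue
            L[i, j] = f_contact(counts, i, j) / fe
    return CrosslinkMatrix(species=counts.species, L=L)


def temperature_sweep(
    trajectories: dict[float, list[Trajectory]],
    min_fraction: float = 0.5,
    anisotropic_only: bool = False,
) -> list[CrosslinkMatrix]:
    """Replicate-averaged crosslink matrices per temperature.

    Per replicate, L is averaged over snapshots with a condensate present;
    replicates without any such snapshot are dropped, and temperatures with
    no usable replicate are skipped with a warning (the system is outside
    its two-phase regime there).
    """
    out: list[CrosslinkMatrix] = []
    for T in sorted(trajectories):
        per_rep: list[np.ndarray] = []
        species: tuple[str, ...] | None = None
        for traj in trajectories[T]:
            frames: list[np.ndarray] = []
            species = traj.system.species_names
            for i in range(len(traj.frames)):
                state = traj.state_at(i)
                cond = find_condensate(state, min_fraction=min_fraction)
                if not cond.is_condensate:
                    continue
                counts = count_contacts(
                    state, cond.chains, anisotropic_only=anisotropic_only
                )
                frames.append(crosslink_L(counts).L)
            if frames:
                per_rep.append(np.nanmean(np.stack(frames), axis=0))
        if not per_rep:
            warnings.warn(f"no condensate at T={T}; temperature skipped")
            continue
        stack = np.stack(per_rep)
        mean = np.nanmean(stack, axis=0)
        n = len(per_rep)
        stderr = (
            np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n)
            if n > 1
            else np.full_like(mean, np.nan)
        )
        out.append(
            CrosslinkMatrix(
                species=species,
                L=mean,
                temperature=T,
                stderr=stderr,
                n_replicates=n,
            )
        )
    return out
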