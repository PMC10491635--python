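"""Metropolis Monte Carlo engine for multichain lattice systems.

One bead per residue on a periodic cubic lattice; vacant sites are solvent.
Bonds and contacts both use the 26-site neighborhood (generalized
bond-fluctuation conventions): consecutive beads of a chain occupy distinct
sites whose coordinates differ by at most one per axis under the periodic
minimum image, and the same neighborhood defines nonbonded contacts.
Bonded neighbors are excluded from contact energy.

Anisotropic interactions are realized as exclusive pairwise partnerships
(at most one partner per bead, partners must be lattice neighbors) that are
formed and broken by a dedicated rewire move.

Moves are accepted with probability min[1, exp(-dE/T)] where T is the
reduced temperature (k_B = 1).  The inner loops are numba-compiled; the
Python layer owns seeding, snapshots and bookkeeping checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .sequence_model import ChainSpec, InteractionTable, electrostatic_forms

__all__ = [
    "LatticeState",
    "System",
    "SimulationConfig",
    "Trajectory",
    "Frame",
    "SeedingError",
    "select_chain_counts",
    "init_dense_seed",
    "run_simulation",
    "total_energy",
    "acceptance_probability",
    "metropolis_step",
    "DEFAULT_MOVE_WEIGHTS",
    "MOVE_NAMES",
]


class SeedingError(RuntimeError):
    """Raised when dense-seed chain placement fails repeatedly."""


# The 26 neighbor offsets of the cubic lattice, fixed ordering.
_OFFS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)

MOVE_NAMES = (
    "local",
    "end_regrowth",
    "reptation",
    "crankshaft",
    "translation",
    "cluster",
    "rewire",
)

#: Default move weights.  These are sampling parameters, not physics.
DEFAULT_MOVE_WEIGHTS: dict[str, float] = {
    "local": 4.0,
    "end_regrowth": 2.0,
    "reptation": 2.0,
    "crankshaft": 1.0,
    "translation": 1.0,
    "cluster": 1.0,
    "rewire": 2.0,
}


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _mind(a, b, L):
    d = (a - b) % L
    if d > L // 2:
        d -= L
    return d


@njit(cache=False, inline="always")
def _is_neighbor(ax, ay, az, bx, by, bz, L):
    dx = _mind(ax, bx, L)
    if dx > 1 or dx < -1:
        return False
    dy = _mind(ay, by, L)
    if dy > 1 or dy < -1:
        return False
    dz = _mind(az, bz, L)
    if dz > 1 or dz < -1:
        return False
    return not (dx == 0 and dy == 0 and dz == 0)


@njit(cache=False)
def _env_energy(
    x, y, z, self_bead, skip_a, skip_b,
    occ, chain_of_bead, species_of_chain, restype, iso, elec, L,
):
    """Nonbonded isotropic+electrostatic energy of a bead placed at (x,y,z).

    ``self_bead`` is ignored among neighbors (its old site may still be
    occupied); ``skip_a``/``skip_b`` are bonded-neighbor bead indices (-1 for
    none), excluded from contact energy.
    """
    rt = restype[self_bead]
    sp = species_of_chain[chain_of_bead[self_bead]]
    e = 0.0
    for k in range(26):
        qx = (x + _OFFS[k, 0]) % L
        qy = (y + _OFFS[k, 1]) % L
        qz = (z + _OFFS[k, 2]) % L
        b = occ[qx, qy, qz]
        if b < 0 or b == self_bead or b == skip_a or b == skip_b:
            continue
        e += iso[rt, restype[b]] + elec[sp, species_of_chain[chain_of_bead[b]]]
    return e


@njit(cache=False)
def _total_energy_kernel(
    positions, occ, chain_of_bead, species_of_chain, restype, partner,
    iso, aniso, elec, L,
):
    n = positions.shape[0]
    e = 0.0
    for b in range(n):
        x, y, z = positions[b, 0], positions[b, 1], positions[b, 2]
        cb = chain_of_bead[b]
        sb = species_of_chain[cb]
        rb = restype[b]
        for k in range(26):
            qx = (x + _OFFS[k, 0]) % L
            qy = (y + _OFFS[k, 1]) % L
            qz = (z + _OFFS[k, 2]) % L
            b2 = occ[qx, qy, qz]
            if b2 <= b:
                continue
            if chain_of_bead[b2] == cb and (b2 - b == 1 or b - b2 == 1):
                continue
            e += iso[rb, restype[b2]] + elec[sb, species_of_chain[chain_of_bead[b2]]]
        pb = partner[b]
        if pb > b:
            e += aniso[rb, restype[pb]]
    return e


@njit(cache=False)
def _bond_ok(qx, qy, qz, b, lo, hi, positions, L):
    if lo >= 0:
        if not _is_neighbor(qx, qy, qz, positions[lo, 0], positions[lo, 1], positions[lo, 2], L):
            return False
    if hi >= 0:
        if not _is_neighbor(qx, qy, qz, positions[hi, 0], positions[hi, 1], positions[hi, 2], L):
            return False
    return True


@njit(cache=False)
def _apply_partner_break(b, partner):
    pb = partner[b]
    if pb >= 0:
        partner[b] = -1
        partner[pb] = -1


@njit(cache=False)
def _try_displace(
    b, qx, qy, qz, lo, hi,
    positions, occ, chain_of_bead, species_of_chain, restype, partner,
    iso, aniso, elec, L, T,
):
    """Shared Metropolis core for single-bead moves (local/end/crankshaft).

    The target site must already be checked empty and bond-valid by the
    caller.  Returns the applied energy change (0.0 on rejection) and an
    acceptance flag.
    """
    x, y, z = positions[b, 0], positions[b, 1], positions[b, 2]
    e_old = _env_energy(x, y, z, b, lo, hi, occ, chain_of_bead,
                        species_of_chain, restype, iso, elec, L)
    e_new = _env_energy(qx, qy, qz, b, lo, hi, occ, chain_of_bead,
                        species_of_chain, restype, iso, elec, L)
    pb = partner[b]
    keep_partner = False
    if pb >= 0:
        ea = aniso[restype[b], restype[pb]]
        e_old += ea
        if _is_neighbor(qx, qy, qz, positions[pb, 0], positions[pb, 1],
                        positions[pb, 2], L):
            e_new += ea
            keep_partner = True
    d_e = e_new - e_old
    if d_e <= 0.0 or np.random.random() < math.exp(-d_e / T):
        occ[x, y, z] = -1
        occ[qx, qy, qz] = b
        positions[b, 0] = qx
        positions[b, 1] = qy
        positions[b, 2] = qz
        if pb >= 0 and not keep_partner:
            partner[b] = -1
            partner[pb] = -1
        return d_e, True
    return 0.0, False


@njit(cache=False)
def _try_local(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T,
):
    n = positions.shape[0]
    b = np.random.randint(0, n)
    k = np.random.randint(0, 26)
    qx = (positions[b, 0] + _OFFS[k, 0]) % L
    qy = (positions[b, 1] + _OFFS[k, 1]) % L
    qz = (positions[b, 2] + _OFFS[k, 2]) % L
    if occ[qx, qy, qz] >= 0:
        return 0.0, False
    c = chain_of_bead[b]
    lo = b - 1 if b - 1 >= chain_starts[c] else -1
    hi = b + 1 if b + 1 < chain_starts[c + 1] else -1
    if not _bond_ok(qx, qy, qz, b, lo, hi, positions, L):
        return 0.0, False
    return _try_displace(b, qx, qy, qz, lo, hi, positions, occ, chain_of_bead,
                         species_of_chain, restype, partner, iso, aniso, elec, L, T)


@njit(cache=False)
def _try_end_regrowth(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T,
):
    nc = chain_starts.shape[0] - 1
    c = np.random.randint(0, nc)
    s, e = chain_starts[c], chain_starts[c + 1]
    if e - s < 2:
        return 0.0, False
    if np.random.random() < 0.5:
        b, anchor = s, s + 1
    else:
        b, anchor = e - 1, e - 2
    k = np.random.randint(0, 26)
    qx = (positions[anchor, 0] + _OFFS[k, 0]) % L
    qy = (positions[anchor, 1] + _OFFS[k, 1]) % L
    qz = (positions[anchor, 2] + _OFFS[k, 2]) % L
    if occ[qx, qy, qz] >= 0:
        return 0.0, False
    return _try_displace(b, qx, qy, qz, anchor, -1, positions, occ,
                         chain_of_bead, species_of_chain, restype, partner,
                         iso, aniso, elec, L, T)


@njit(cache=False)
def _try_crankshaft(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T,
):
    n = positions.shape[0]
    b = np.random.randint(0, n)
    c = chain_of_bead[b]
    if b == chain_starts[c] or b == chain_starts[c + 1] - 1:
        return 0.0, False
    k = np.random.randint(0, 26)
    qx = (positions[b - 1, 0] + _OFFS[k, 0]) % L
    qy = (positions[b - 1, 1] + _OFFS[k, 1]) % L
    qz = (positions[b - 1, 2] + _OFFS[k, 2]) % L
    if occ[qx, qy, qz] >= 0:
        return 0.0, False
    if not _is_neighbor(qx, qy, qz, positions[b + 1, 0], positions[b + 1, 1],
                        positions[b + 1, 2], L):
        return 0.0, False
    return _try_displace(b, qx, qy, qz, b - 1, b + 1, positions, occ,
                         chain_of_bead, species_of_chain, restype, partner,
                         iso, aniso, elec, L, T)


@njit(cache=False)
def _try_reptation(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, chain_is_homopolymer, iso, aniso, elec, L, T,
):
    # Slithering-snake move; restricted to homopolymer chains (a residue
    # remap would be required for heteropolymers) without anisotropic
    # partnerships (bead indices shift under the move).
    nc = chain_starts.shape[0] - 1
    c = np.random.randint(0, nc)
    if not chain_is_homopolymer[c]:
        return 0.0, False
    s, e = chain_starts[c], chain_starts[c + 1]
    if e - s < 2:
        return 0.0, False
    for i in range(s, e):
        if partner[i] >= 0:
            return 0.0, False
    head_dir = np.random.random() < 0.5
    if head_dir:
        tail, head = s, e - 1
        tail_nb = s + 1
    else:
        tail, head = e - 1, s
        tail_nb = e - 2
    k = np.random.randint(0, 26)
    qx = (positions[head, 0] + _OFFS[k, 0]) % L
    qy = (positions[head, 1] + _OFFS[k, 1]) % L
    qz = (positions[head, 2] + _OFFS[k, 2]) % L
    tx, ty, tz = positions[tail, 0], positions[tail, 1], positions[tail, 2]
    o = occ[qx, qy, qz]
    if o >= 0 and o != tail:
        return 0.0, False
    e_old = _env_energy(tx, ty, tz, tail, tail_nb, -1, occ, chain_of_bead,
                        species_of_chain, restype, iso, elec, L)
    occ[tx, ty, tz] = -1
    if occ[qx, qy, qz] >= 0:  # target was the vacated tail site
        occ[tx, ty, tz] = tail
        return 0.0, False
    e_new = _env_energy(qx, qy, qz, tail, head, -1, occ, chain_of_bead,
                        species_of_chain, restype, iso, elec, L)
    d_e = e_new - e_old
    if d_e <= 0.0 or np.random.random() < math.exp(-d_e / T):
        if head_dir:
            for i in range(s, e - 1):
                positions[i, 0] = positions[i + 1, 0]
                positions[i, 1] = positions[i + 1, 1]
                positions[i, 2] = positions[i + 1, 2]
                occ[positions[i, 0], positions[i, 1], positions[i, 2]] = i
            positions[e - 1, 0] = qx
            positions[e - 1, 1] = qy
            positions[e - 1, 2] = qz
            occ[qx, qy, qz] = e - 1
        else:
            for i in range(e - 1, s, -1):
                positions[i, 0] = positions[i - 1, 0]
                positions[i, 1] = positions[i - 1, 1]
                positions[i, 2] = positions[i - 1, 2]
                occ[positions[i, 0], positions[i, 1], positions[i, 2]] = i
            positions[s, 0] = qx
            positions[s, 1] = qy
            positions[s, 2] = qz
            occ[qx, qy, qz] = s
        return d_e, True
    occ[tx, ty, tz] = tail
    return 0.0, False


@njit(cache=False)
def _chain_external_energy(
    c, chain_starts, positions, occ, chain_of_bead, species_of_chain, restype,
    iso, elec, L,
):
    s, e = chain_starts[c], chain_starts[c + 1]
    sp = species_of_chain[c]
    en = 0.0
    for b in range(s, e):
        rb = restype[b]
        for k in range(26):
            qx = (positions[b, 0] + _OFFS[k, 0]) % L
            qy = (positions[b, 1] + _OFFS[k, 1]) % L
            qz = (positions[b, 2] + _OFFS[k, 2]) % L
            b2 = occ[qx, qy, qz]
            if b2 < 0:
                continue
            if chain_of_bead[b2] == c:
                continue
            en += iso[rb, restype[b2]] + elec[sp, species_of_chain[chain_of_bead[b2]]]
    return en


@njit(cache=False)
def _try_translation(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T,
):
    nc = chain_starts.shape[0] - 1
    c = np.random.randint(0, nc)
    s, e = chain_starts[c], chain_starts[c + 1]
    for b in range(s, e):
        pb = partner[b]
        if pb >= 0 and chain_of_bead[pb] != c:
            return 0.0, False  # cross-chain partnership pins the chain
    k = np.random.randint(0, 26)
    dx, dy, dz = _OFFS[k, 0], _OFFS[k, 1], _OFFS[k, 2]
    for b in range(s, e):
        qx = (positions[b, 0] + dx) % L
        qy = (positions[b, 1] + dy) % L
        qz = (positions[b, 2] + dz) % L
        o = occ[qx, qy, qz]
        if o >= 0 and chain_of_bead[o] != c:
            return 0.0, False
    e_old = _chain_external_energy(c, chain_starts, positions, occ,
                                   chain_of_bead, species_of_chain, restype,
                                   iso, elec, L)
    for b in range(s, e):
        occ[positions[b, 0], positions[b, 1], positions[b, 2]] = -1
    for b in range(s, e):
        positions[b, 0] = (positions[b, 0] + dx) % L
        positions[b, 1] = (positions[b, 1] + dy) % L
        positions[b, 2] = (positions[b, 2] + dz) % L
        occ[positions[b, 0], positions[b, 1], positions[b, 2]] = b
    e_new = _chain_external_energy(c, chain_starts, positions, occ,
                                   chain_of_bead, species_of_chain, restype,
                                   iso, elec, L)
    d_e = e_new - e_old
    if d_e <= 0.0 or np.random.random() < math.exp(-d_e / T):
        return d_e, True
    for b in range(s, e):
        occ[positions[b, 0], positions[b, 1], positions[b, 2]] = -1
    for b in range(s, e):
        positions[b, 0] = (positions[b, 0] - dx) % L
        positions[b, 1] = (positions[b, 1] - dy) % L
        positions[b, 2] = (positions[b, 2] - dz) % L
        occ[positions[b, 0], positions[b, 1], positions[b, 2]] = b
    return 0.0, False


@njit(cache=False)
def _try_cluster(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T, in_cluster, stack, max_cluster,
):
    # Rigid translation of a maximal connected cluster of chains.  Because
    # the cluster is maximal it has no external contacts before the move; a
    # move that would create any is rejected, so dE = 0 and the move only
    # diffuses isolated clusters.  Clusters larger than ``max_cluster``
    # chains abort as rejected attempts: translating a system-spanning
    # condensate is physically irrelevant and dominates the cost otherwise.
    nc = chain_starts.shape[0] - 1
    c0 = np.random.randint(0, nc)
    for i in range(nc):
        in_cluster[i] = False
    in_cluster[c0] = True
    stack[0] = c0
    top = 1
    n_in = 1
    while top > 0:
        top -= 1
        c = stack[top]
        for b in range(chain_starts[c], chain_starts[c + 1]):
            for k in range(26):
                qx = (positions[b, 0] + _OFFS[k, 0]) % L
                qy = (positions[b, 1] + _OFFS[k, 1]) % L
                qz = (positions[b, 2] + _OFFS[k, 2]) % L
                b2 = occ[qx, qy, qz]
                if b2 < 0:
                    continue
                c2 = chain_of_bead[b2]
                if not in_cluster[c2]:
                    in_cluster[c2] = True
                    stack[top] = c2
                    top += 1
                    n_in += 1
                    if n_in > max_cluster:
                        return 0.0, False
    k = np.random.randint(0, 26)
    dx, dy, dz = _OFFS[k, 0], _OFFS[k, 1], _OFFS[k, 2]
    n = positions.shape[0]
    # collision check against non-cluster beads
    for b in range(n):
        if not in_cluster[chain_of_bead[b]]:
            continue
        qx = (positions[b, 0] + dx) % L
        qy = (positions[b, 1] + dy) % L
        qz = (positions[b, 2] + dz) % L
        o = occ[qx, qy, qz]
        if o >= 0 and not in_cluster[chain_of_bead[o]]:
            return 0.0, False
    for b in range(n):
        if in_cluster[chain_of_bead[b]]:
            occ[positions[b, 0], positions[b, 1], positions[b, 2]] = -1
    for b in range(n):
        if in_cluster[chain_of_bead[b]]:
            positions[b, 0] = (positions[b, 0] + dx) % L
            positions[b, 1] = (positions[b, 1] + dy) % L
            positions[b, 2] = (positions[b, 2] + dz) % L
            occ[positions[b, 0], positions[b, 1], positions[b, 2]] = b
    # reject if the move created a contact with a non-cluster bead
    created = False
    for b in range(n):
        if created:
            break
        if not in_cluster[chain_of_bead[b]]:
            continue
        for k2 in range(26):
            qx = (positions[b, 0] + _OFFS[k2, 0]) % L
            qy = (positions[b, 1] + _OFFS[k2, 1]) % L
            qz = (positions[b, 2] + _OFFS[k2, 2]) % L
            o = occ[qx, qy, qz]
            if o >= 0 and not in_cluster[chain_of_bead[o]]:
                created = True
                break
    if not created:
        return 0.0, True
    for b in range(n):
        if in_cluster[chain_of_bead[b]]:
            occ[positions[b, 0], positions[b, 1], positions[b, 2]] = -1
    for b in range(n):
        if in_cluster[chain_of_bead[b]]:
            positions[b, 0] = (positions[b, 0] - dx) % L
            positions[b, 1] = (positions[b, 1] - dy) % L
            positions[b, 2] = (positions[b, 2] - dz) % L
            occ[positions[b, 0], positions[b, 1], positions[b, 2]] = b
    return 0.0, False


@njit(cache=False)
def _try_rewire(
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, iso, aniso, elec, L, T,
):
    n = positions.shape[0]
    a = np.random.randint(0, n)
    k = np.random.randint(0, 26)
    qx = (positions[a, 0] + _OFFS[k, 0]) % L
    qy = (positions[a, 1] + _OFFS[k, 1]) % L
    qz = (positions[a, 2] + _OFFS[k, 2]) % L
    b = occ[qx, qy, qz]
    if b < 0:
        return 0.0, False
    if chain_of_bead[a] == chain_of_bead[b] and (b - a == 1 or a - b == 1):
        return 0.0, False  # bonded pair cannot be an anisotropic partner
    ea = aniso[restype[a], restype[b]]
    if partner[a] == b:
        d_e = -ea
        if d_e <= 0.0 or np.random.random() < math.exp(-d_e / T):
            partner[a] = -1
            partner[b] = -1
            return d_e, True
        return 0.0, False
    if partner[a] < 0 and partner[b] < 0:
        d_e = ea
        if d_e <= 0.0 or np.random.random() < math.exp(-d_e / T):
            partner[a] = b
            partner[b] = a
            return d_e, True
        return 0.0, False
    return 0.0, False


@njit(cache=False)
def _mc_block(
    seed, nsteps,
    positions, occ, chain_starts, chain_of_bead, species_of_chain, restype,
    partner, chain_is_homopolymer, iso, aniso, elec, L, T, move_cum,
    in_cluster, stack, max_cluster,
):
    np.random.seed(seed)
    d_total = 0.0
    n_accept = 0
    for _ in range(nsteps):
        u = np.random.random()
        m = 0
        while move_cum[m] < u:
            m += 1
        if m == 0:
            d_e, acc = _try_local(positions, occ, chain_starts, chain_of_bead,
                                  species_of_chain, restype, partner, iso,
                                  aniso, elec, L, T)
        elif m == 1:
            d_e, acc = _try_end_regrowth(positions, occ, chain_starts,
                                         chain_of_bead, species_of_chain,
                                         restype, partner, iso, aniso, elec, L, T)
        elif m == 2:
            d_e, acc = _try_reptation(positions, occ, chain_starts,
                                      chain_of_bead, species_of_chain, restype,
                                      partner, chain_is_homopolymer, iso,
                                      aniso, elec, L, T)
        elif m == 3:
            d_e, acc = _try_crankshaft(positions, occ, chain_starts,
                                       chain_of_bead, species_of_chain,
                                       restype, partner, iso, aniso, elec, L, T)
        elif m == 4:
            d_e, acc = _try_translation(positions, occ, chain_starts,
                                        chain_of_bead, species_of_chain,
                                        restype, partner, iso, aniso, elec, L, T)
        elif m == 5:
            d_e, acc = _try_cluster(positions, occ, chain_starts, chain_of_bead,
                                    species_of_chain, restype, partner, iso,
                                    aniso, elec, L, T, in_cluster, stack,
                                    max_cluster)
        else:
            d_e, acc = _try_rewire(positions, occ, chain_starts, chain_of_bead,
                                   species_of_chain, restype, partner, iso,
                                   aniso, elec, L, T)
        d_total += d_e
        if acc:
            n_accept += 1
    return d_total, n_accept


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

@dataclass
class System:
    """A set of species with chain counts, an interaction table and a box."""

    species: tuple[ChainSpec, ...]
    counts: tuple[int, ...]
    table: InteractionTable
    L: int

    def __post_init__(self) -> None:
        if len(self.species) != len(self.counts):
            raise ValueError("species and counts must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("chain counts must be nonnegative")
        if self.L < 4:
            raise ValueError("lattice edge must be at least 4 sites")
        self._compile()

    def _compile(self) -> None:
        table = self.table
        restype = []
        chain_starts = [0]
        species_of_chain = []
        for si, (spec, count) in enumerate(zip(self.species, self.counts)):
            codes = [table.index(r) for r in spec.residues]
            for _ in range(count):
                restype.extend(codes)
                chain_starts.append(chain_starts[-1] + spec.length)
                species_of_chain.append(si)
        self.restype = np.asarray(restype, dtype=np.int64)
        self.chain_starts = np.asarray(chain_starts, dtype=np.int64)
        self.species_of_chain = np.asarray(species_of_chain, dtype=np.int64)
        self.chain_of_bead = np.repeat(
            np.arange(len(species_of_chain), dtype=np.int64),
            np.diff(self.chain_starts),
        )
        nsp = len(self.species)
        form = electrostatic_forms[table.electrostatic_form]
        elec = np.zeros((nsp, nsp))
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                elec[i, j] = form(a.ncpr, b.ncpr, table.lambda_el)
        self.elec = elec
        self.iso = np.ascontiguousarray(table.iso, dtype=np.float64)
        self.aniso = np.ascontiguousarray(table.aniso, dtype=np.float64)
        self.chain_is_homopolymer = np.array(
            [len(set(self.species[s].residues)) == 1 for s in species_of_chain],
            dtype=np.bool_,
        )

    @property
    def n_beads(self) -> int:
        return int(self.chain_starts[-1])

    @property
    def n_chains(self) -> int:
        return len(self.species_of_chain)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def volume_fraction(self) -> float:
        return self.n_beads / self.L**3


@dataclass
class LatticeState:
    """Bead coordinates plus occupancy, partnerships and cached energy."""

    system: System
    positions: np.ndarray  # (n_beads, 3) int64 in [0, L)
    partner: np.ndarray  # (n_beads,) int64, -1 = none
    temperature: float
    occ: np.ndarray = field(default=None, repr=False)  # (L,L,L) int64
    total_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.occ is None:
            self.occ = self._build_occ()
            self.total_energy = total_energy(self)

    def _build_occ(self) -> np.ndarray:
        L = self.system.L
        occ = np.full((L, L, L), -1, dtype=np.int64)
        for b, (x, y, z) in enumerate(self.positions):
            if occ[x, y, z] != -1:
                raise ValueError(f"site {(x, y, z)} doubly occupied")
            occ[x, y, z] = b
        return occ

    @property
    def L(self) -> int:
        return self.system.L

    def copy(self) -> "LatticeState":
        return LatticeState(
            system=self.system,
            positions=self.positions.copy(),
            partner=self.partner.copy(),
            temperature=self.temperature,
            occ=self.occ.copy(),
            total_energy=self.total_energy,
        )

    def chain_positions(self, c: int) -> np.ndarray:
        s, e = self.system.chain_starts[c], self.system.chain_starts[c + 1]
        return self.positions[s:e]

    def validate(self, energy_tol: float = 1e-9) -> None:
        """Check all state invariants; raises AssertionError on violation."""
        sys_ = self.system
        L = sys_.L
        pos = self.positions
        assert pos.shape == (sys_.n_beads, 3)
        assert ((pos >= 0) & (pos < L)).all(), "coordinates outside the box"
        occ = self._build_occ()  # raises on excluded-volume violation
        assert (occ == self.occ).all(), "occupancy grid out of sync"
        for c in range(sys_.n_chains):
            p = self.chain_positions(c)
            d = (p[1:] - p[:-1]) % L
            d = np.where(d > L // 2, d - L, d)
            assert (np.abs(d) <= 1).all(), f"bond broken in chain {c}"
            assert (np.abs(d).sum(axis=1) > 0).all(), f"zero bond in chain {c}"
        for b, pb in enumerate(self.partner):
            if pb >= 0:
                assert self.partner[pb] == b, "partnership not mutual"
                assert _is_neighbor(
                    pos[b, 0], pos[b, 1], pos[b, 2],
                    pos[pb, 0], pos[pb, 1], pos[pb, 2], L,
                ), "partners not lattice neighbors"
        ref = total_energy(self)
        assert abs(ref - self.total_energy) <= energy_tol, (
            f"cached energy {self.total_energy} vs recomputed {ref}"
        )


def total_energy(state: LatticeState, table: InteractionTable | None = None) -> float:
    """Full recomputation of the reduced energy of a state.

    Sums iso + electrostatic terms over unordered nonbonded bead pairs in
    26-neighborhood contact, plus anisotropic terms over partnered pairs.
    Serves as the oracle for the engine's incremental bookkeeping.
    """
    sys_ = state.system
    if table is not None and table is not sys_.table:
        sys_ = System(sys_.species, sys_.counts, table, sys_.L)
    return float(
        _total_energy_kernel(
            state.positions, state.occ, sys_.chain_of_bead,
            sys_.species_of_chain, sys_.restype, state.partner,
            sys_.iso, sys_.aniso, sys_.elec, sys_.L,
        )
    )


# ---------------------------------------------------------------------------
# configuration and chain-count selection
# ---------------------------------------------------------------------------

def select_chain_counts(
    species_ratios: Sequence[float],
    chain_lengths: Sequence[int],
    L: int,
    target_phi: float,
) -> tuple[int, ...]:
    """Integer chain counts matching a molecule-number ratio and a target
    total bead volume fraction.

    The smallest integer repeat unit realizing the ratio pattern is scaled
    by the positive integer multiplier that minimizes |realized phi -
    target_phi|; ties break toward fewer chains.
    """
    if len(species_ratios) != len(chain_lengths):
        raise ValueError("ratios and lengths must align")
    if not 0 < target_phi < 1:
        raise ValueError("target_phi must be in (0, 1)")
    if abs(sum(species_ratios) - 1.0) > 1e-9:
        raise ValueError("species ratios must sum to 1")
    active = [i for i, r in enumerate(species_ratios) if r > 0]
    fracs = [Fraction(species_ratios[i]).limit_denominator(10**6) for i in active]
    denom_lcm = 1
    for f in fracs:
        denom_lcm = denom_lcm * f.denominator // math.gcd(denom_lcm, f.denominator)
    base = [int(f * denom_lcm) for f in fracs]
    g = 0
    for b in base:
        g = math.gcd(g, b)
    base = [b // g for b in base]
    unit_beads = sum(b * chain_lengths[i] for b, i in zip(base, active))
    n_sites = L**3
    if unit_beads > n_sites:
        raise ValueError("one repeat unit exceeds the lattice capacity")
    m_max = max(1, int(math.ceil(2 * target_phi * n_sites / unit_beads)))
    best_m, best_err = None, None
    for m in range(1, m_max + 1):
        err = abs(m * unit_beads / n_sites - target_phi)
        if best_err is None or err < best_err:  # strict: ties keep fewer chains
            best_m, best_err = m, err
    counts = [0] * len(species_ratios)
    for b, i in zip(base, active):
        counts[i] = b * best_m
    return tuple(counts)


@dataclass
class SimulationConfig:
    """Everything needed to run one simulation campaign."""

    lattice_size: int
    species: tuple[ChainSpec, ...]
    chain_counts: tuple[int, ...]
    table: InteractionTable
    temperatures: tuple[float, ...]
    total_steps: int
    analysis_start: int | None = None
    snapshot_interval: int | None = None
    seed_box: int = 35
    move_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS)
    )
    seed: int = 0
    scaled_down: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.analysis_start is None:
            self.analysis_start = self.total_steps // 2
        if self.snapshot_interval is None:
            remaining = max(1, self.total_steps - self.analysis_start)
            self.snapshot_interval = max(1, remaining // 10)
        if not 0 <= self.analysis_start < self.total_steps:
            raise ValueError("analysis_start must lie in [0, total_steps)")
        if any(c <= 0 for c in self.chain_counts):
            raise ValueError("chain counts must be positive")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")
        unknown = set(self.move_weights) - set(MOVE_NAMES)
        if unknown:
            raise ValueError(f"unknown move weights: {sorted(unknown)}")

    def build_system(self) -> System:
        return System(
            species=tuple(self.species),
            counts=tuple(self.chain_counts),
            table=self.table,
            L=self.lattice_size,
        )

    def move_cumulative(self) -> np.ndarray:
        w = np.array(
            [float(self.move_weights.get(name, 0.0)) for name in MOVE_NAMES]
        )
        if w.sum() <= 0:
            raise ValueError("move weights must have positive total")
        cum = np.cumsum(w / w.sum())
        cum[-1] = 1.0 + 1e-12  # guard against float round-down
        return cum


# ---------------------------------------------------------------------------
# dense seeding
# ---------------------------------------------------------------------------

def _grow_chain(occ, length, allowed, start_sites, rng, max_backtrack=200):
    """Self-avoiding growth of one chain inside ``allowed`` sites.

    ``allowed`` is a callable (x, y, z) -> bool; ``start_sites`` an (m, 3)
    array of candidate first-bead sites.  Returns the list of sites or None
    on failure.  Backtracking removes the last bead and retries.
    """
    L = occ.shape[0]
    path = []
    start_found = False
    for i in rng.permutation(len(start_sites))[:4000]:
        x, y, z = start_sites[i]
        if occ[x, y, z] == -1:
            path = [(int(x), int(y), int(z))]
            occ[x, y, z] = -2  # provisional marker
            start_found = True
            break
    if not start_found:
        return None
    backtracks = 0
    while len(path) < length:
        x, y, z = path[-1]
        order = rng.permutation(26)
        placed = False
        for k in order:
            qx = (x + _OFFS[k, 0]) % L
            qy = (y + _OFFS[k, 1]) % L
            qz = (z + _OFFS[k, 2]) % L
            if occ[qx, qy, qz] == -1 and allowed(qx, qy, qz):
                path.append((int(qx), int(qy), int(qz)))
                occ[qx, qy, qz] = -2
                placed = True
                break
        if not placed:
            backtracks += 1
            if backtracks > max_backtrack or len(path) == 1:
                for px, py, pz in path:
                    occ[px, py, pz] = -1
                return None
            px, py, pz = path.pop()
            occ[px, py, pz] = -1
    return path


def init_dense_seed(
    config: SimulationConfig,
    rng: np.random.Generator,
    temperature: float | None = None,
) -> LatticeState:
    """Place all chains by self-avoiding growth in a centered sub-box.

    Seeding all chains in a small sub-box (default edge 35, clipped to the
    lattice) nucleates a single dense region and accelerates equilibration
    of the two-phase system.
    """
    system = config.build_system()
    L = system.L
    s = min(config.seed_box, L)
    if system.n_beads > s**3:
        raise SeedingError(
            f"{system.n_beads} beads cannot fit in the {s}^3 seed sub-box; "
            "increase seed_box"
        )
    lo = (L - s) // 2
    hi = lo + s

    def allowed(x, y, z):
        return lo <= x < hi and lo <= y < hi and lo <= z < hi

    grid = np.arange(lo, hi)
    start_sites = (
        np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1)
        .reshape(-1, 3)
    )
    lengths = [
        int(system.chain_starts[c + 1] - system.chain_starts[c])
        for c in range(system.n_chains)
    ]
    for _attempt in range(20):
        occ = np.full((L, L, L), -1, dtype=np.int64)
        chains: list[list[tuple[int, int, int]]] = []
        ok = True
        for length in lengths:
            path = None
            for _retry in range(50):
                path = _grow_chain(occ, length, allowed, start_sites, rng)
                if path is not None:
                    break
            if path is None:
                ok = False
                break
            chains.append(path)
        if ok:
            positions = np.array(
                [site for path in chains for site in path], dtype=np.int64
            )
            state = LatticeState(
                system=system,
                positions=positions,
                partner=np.full(system.n_beads, -1, dtype=np.int64),
                temperature=(
                    temperature
                    if temperature is not None
                    else (config.temperatures[0] if config.temperatures else 1.0)
                ),
            )
            return state
    raise SeedingError(
        "chain placement failed repeatedly; use a larger seed sub-box"
    )


# ---------------------------------------------------------------------------
# running
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    step: int
    positions: np.ndarray
    partner: np.ndarray
    energy: float


@dataclass
class Trajectory:
    """Snapshots of one simulation at one temperature."""

    system: System
    temperature: float
    seed: int
    total_steps: int
    analysis_start: int
    frames: list[Frame] = field(default_factory=list)

    def state_at(self, i: int) -> LatticeState:
        fr = self.frames[i]
        return LatticeState(
            system=self.system,
            positions=fr.positions.copy(),
            partner=fr.partner.copy(),
            temperature=self.temperature,
        )

    @property
    def energies(self) -> np.ndarray:
        return np.array([fr.energy for fr in self.frames])

    # -- TSV round trip ----------------------------------------------------

    def to_tsv(self, path) -> None:
        sys_ = self.system
        residues = [r for spec, cnt in zip(sys_.species, sys_.counts)
                    for _ in range(cnt) for r in spec.residues]
        names = sys_.species_names
        with open(path, "w") as fh:
            fh.write(f"# lattice_size={sys_.L}\n")
            fh.write(f"# temperature={self.temperature!r}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write(f"# total_steps={self.total_steps}\n")
            fh.write(f"# analysis_start={self.analysis_start}\n")
            fh.write(
                "# snapshot_steps="
                + ",".join(str(fr.step) for fr in self.frames) + "\n"
            )
            fh.write(
                "# snapshot_energies="
                + ",".join(repr(fr.energy) for fr in self.frames) + "\n"
            )
            fh.write(
                "snapshot\tchain_id\tspecies\tbead_index\tresidue\tx\ty\tz\taniso_partner\n"
            )
            for snap, fr in enumerate(self.frames):
                for b in range(sys_.n_beads):
                    c = sys_.chain_of_bead[b]
                    fh.write(
                        f"{snap}\t{c}\t{names[sys_.species_of_chain[c]]}\t"
                        f"{b - sys_.chain_starts[c]}\t{residues[b]}\t"
                        f"{fr.positions[b, 0]}\t{fr.positions[b, 1]}\t"
                        f"{fr.positions[b, 2]}\t{fr.partner[b]}\n"
                    )

    @classmethod
    def from_tsv(cls, path, table: InteractionTable | None = None) -> "Trajectory":
        import pandas as pd

        header: dict[str, str] = {}
        with open(path) as fh:
            skip = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
                header[key.strip()] = value
        df = pd.read_csv(path, sep="\t", comment="#")
        L = int(header["lattice_size"])
        temperature = float(header.get("temperature", 1.0))
        seed = int(header.get("seed", 0))
        snap0 = df[df["snapshot"] == df["snapshot"].min()]
        specs: list[ChainSpec] = []
        counts: list[int] = []
        seen: dict[str, int] = {}
        for c, grp in snap0.groupby("chain_id", sort=True):
            name = str(grp["species"].iloc[0])
            residues = tuple(
                str(r) for r in grp.sort_values("bead_index")["residue"]
            )
            if name in seen:
                if seen[name] != len(specs) - 1:
                    raise ValueError(
                        "chains of a species must be contiguous in the TSV"
                    )
                counts[seen[name]] += 1
            else:
                seen[name] = len(specs)
                # descriptors unknown from a trajectory alone; stored neutral
                specs.append(
                    ChainSpec(name=name, residues=residues,
                              length=len(residues), ncpr=0.0, fcr=0.0)
                )
                counts.append(1)
        if table is None:
            alphabet = tuple(sorted({r for s in specs for r in s.residues}))
            k = len(alphabet)
            table = InteractionTable(
                alphabet=alphabet, iso=np.zeros((k, k)), aniso=np.zeros((k, k))
            )
        system = System(tuple(specs), tuple(counts), table, L)
        traj = cls(
            system=system,
            temperature=temperature,
            seed=seed,
            total_steps=int(header.get("total_steps", 0)),
            analysis_start=int(header.get("analysis_start", 0)),
        )
        steps = [int(x) for x in header.get("snapshot_steps", "").split(",") if x]
        energies = [
            float(x) for x in header.get("snapshot_energies", "").split(",") if x
        ]
        order = np.lexsort((df["bead_index"], df["chain_id"], df["snapshot"]))
        df = df.iloc[order]
        for si, (snap, grp) in enumerate(df.groupby("snapshot", sort=True)):
            positions = grp[["x", "y", "z"]].to_numpy(dtype=np.int64)
            partner = grp["aniso_partner"].to_numpy(dtype=np.int64)
            traj.frames.append(
                Frame(
                    step=steps[si] if si < len(steps) else si,
                    positions=positions,
                    partner=partner,
                    energy=energies[si] if si < len(energies) else np.nan,
                )
            )
        return traj


def _block_seeds(seed: int, temp_index: int, n_blocks: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(seed) % (2**31), temp_index])
    return (ss.generate_state(n_blocks) % np.uint32(2**31)).astype(np.int64)


def run_mc(state: LatticeState, n_steps: int, seed: int,
           move_cum: np.ndarray | None = None) -> tuple[float, int]:
    """Advance a state by ``n_steps`` Metropolis attempts.

    Returns (applied energy change, accepted count); the state's cached
    total energy is updated in place.
    """
    if move_cum is None:
        w = np.array([DEFAULT_MOVE_WEIGHTS[name] for name in MOVE_NAMES])
        move_cum = np.cumsum(w / w.sum())
        move_cum[-1] = 1.0 + 1e-12
    sys_ = state.system
    in_cluster = np.zeros(sys_.n_chains, dtype=np.bool_)
    stack = np.zeros(sys_.n_chains, dtype=np.int64)
    max_cluster = max(2, sys_.n_chains // 8)
    d_e, n_acc = _mc_block(
        int(seed) % (2**31), int(n_steps),
        state.positions, state.occ, sys_.chain_starts, sys_.chain_of_bead,
        sys_.species_of_chain, sys_.restype, state.partner,
        sys_.chain_is_homopolymer, sys_.iso, sys_.aniso, sys_.elec,
        sys_.L, state.temperature, move_cum, in_cluster, stack, max_cluster,
    )
    state.total_energy += d_e
    return d_e, n_acc


def run_simulation(
    config: SimulationConfig,
    out_dir=None,
    check_invariants: bool = True,
) -> list[Trajectory]:
    """Run the configured campaign, one independent run per temperature.

    Each temperature gets a fresh dense seed and an independent RNG stream
    derived from the config seed, so runs are reproducible bit-for-bit.
    Snapshots are recorded after the analysis-start step at the configured
    cadence; the cached energy is verified against a full recomputation at
    every snapshot.  When ``out_dir`` is given, each finished temperature's
    trajectory is written immediately (TSV), so an interrupted campaign
    retains all completed temperatures.
    """
    move_cum = config.move_cumulative()
    trajectories: list[Trajectory] = []
    for ti, T in enumerate(config.temperatures):
        seed_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**31), ti, 9173])
        )
        state = init_dense_seed(config, seed_rng, temperature=T)
        sys_ = state.system
        in_cluster = np.zeros(sys_.n_chains, dtype=np.bool_)
        stack = np.zeros(sys_.n_chains, dtype=np.int64)
        max_cluster = max(2, sys_.n_chains // 8)
        snap_steps = list(
            range(config.analysis_start, config.total_steps + 1,
                  config.snapshot_interval)
        )
        if snap_steps[-1] != config.total_steps:
            snap_steps.append(config.total_steps)
        blocks = [snap_steps[0]] + [
            b - a for a, b in zip(snap_steps[:-1], snap_steps[1:])
        ]
        seeds = _block_seeds(config.seed, ti, len(blocks))
        traj = Trajectory(
            system=sys_,
            temperature=T,
            seed=config.seed,
            total_steps=config.total_steps,
            analysis_start=config.analysis_start,
        )
        step = 0
        for bi, nsteps in enumerate(blocks):
            if nsteps > 0:
                d_e, _ = _mc_block(
                    int(seeds[bi]), int(nsteps),
                    state.positions, state.occ, sys_.chain_starts,
                    sys_.chain_of_bead, sys_.species_of_chain, sys_.restype,
                    state.partner, sys_.chain_is_homopolymer,
                    sys_.iso, sys_.aniso, sys_.elec, sys_.L, T,
                    move_cum, in_cluster, stack, max_cluster,
                )
                state.total_energy += d_e
            step += nsteps
            if check_invariants:
                state.validate()
            traj.frames.append(
                Frame(
                    step=step,
                    positions=state.positions.copy(),
                    partner=state.partner.copy(),
                    energy=state.total_energy,
                )
            )
        trajectories.append(traj)
        if out_dir is not None:
            import os

            os.makedirs(out_dir, exist_ok=True)
            traj.to_tsv(
                os.path.join(out_dir, f"traj_T{T:g}_seed{config.seed}.tsv")
            )
    return trajectories


# ---------------------------------------------------------------------------
# single-move API
# ---------------------------------------------------------------------------

def acceptance_probability(d_e: float, temperature: float) -> float:
    """Metropolis criterion: min[1, exp(-dE/T)] with k_B = 1."""
    if d_e <= 0:
        return 1.0
    return math.exp(-d_e / temperature)


@dataclass(frozen=True)
class LocalMove:
    """Single-bead displacement of ``bead`` by a 26-neighborhood offset."""

    bead: int
    offset: tuple[int, int, int]


def metropolis_step(
    state: LatticeState, move: LocalMove, rng: np.random.Generator
) -> bool:
    """Attempt one explicitly specified local move on a state.

    Geometry-invalid proposals count as attempted-and-rejected moves.
    Returns True when the move was accepted; the cached energy is updated
    by dE on acceptance and the state is untouched on rejection.
    """
    sys_ = state.system
    L = sys_.L
    b = move.bead
    p = state.positions[b]
    q = (p + np.asarray(move.offset, dtype=np.int64)) % L
    if state.occ[q[0], q[1], q[2]] >= 0:
        return False
    c = sys_.chain_of_bead[b]
    lo = b - 1 if b - 1 >= sys_.chain_starts[c] else -1
    hi = b + 1 if b + 1 < sys_.chain_starts[c + 1] else -1
    if not _bond_ok(q[0], q[1], q[2], b, lo, hi, state.positions, L):
        return False

    def env(x, y, z):
        return _env_energy(x, y, z, b, lo, hi, state.occ, sys_.chain_of_bead,
                           sys_.species_of_chain, sys_.restype, sys_.iso,
                           sys_.elec, L)

    e_old = env(p[0], p[1], p[2])
    e_new = env(q[0], q[1], q[2])
    pb = int(state.partner[b])
    keep = False
    if pb >= 0:
        ea = sys_.aniso[sys_.restype[b], sys_.restype[pb]]
        e_old += ea
        pp = state.positions[pb]
        if _is_neighbor(q[0], q[1], q[2], pp[0], pp[1], pp[2], L):
            e_new += ea
            keep = True
    d_e = float(e_new - e_old)
    if rng.random() < acceptance_probability(d_e, state.temperature):
        state.occ[p[0], p[1], p[2]] = -1
        state.occ[q[0], q[1], q[2]] = b
        state.positions[b] = q
        if pb >= 0 and not keep:
            state.partner[b] = -1
            state.partner[pb] = -1
        state.total_energy += d_e
        return True
    return False
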