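"""Synthetic inputs with known ground truth for the analysis pipeline.

Generators build condensate-like bead configurations with controlled
mixing statistics (random-mixed or core-shell droplets), noisy logistic
density fields, lever-rule tie-line tables, and preset simulation
configurations for homopolymer scenarios taken from species-pair energy
matrices (all-equal, heterotypic-strong, homotypic-strong, weak-A-A,
length mixtures).  Every generator records its generative ground truth so
analysis modules can be tested closed-loop, and every generator is
deterministic given its seed.

Droplets are packed by lattice-constrained self-avoiding growth inside a
ball whose radius targets an interior volume fraction of ~0.6, a typical
lattice dense-phase density; this is a fixture convention, not a physics
claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .condensate_geometry import RadialProfile, SHELL_WIDTH, logistic
from .lattice_engine import (
    LatticeState,
    SeedingError,
    SimulationConfig,
    System,
    _grow_chain,
    select_chain_counts,
)
from .sequence_model import ChainSpec, InteractionTable

__all__ = [
    "FixtureSpec",
    "make_random_mixed_condensate",
    "make_core_shell_condensate",
    "make_logistic_profile",
    "make_leverrule_table",
    "interaction_table_preset",
    "preset_system",
    "synthetic_plcd_sequence",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# droplet packing
# ---------------------------------------------------------------------------

def _ball_radius(n_beads: int, phi: float) -> float:
    return (3.0 * n_beads / (phi * 4.0 * math.pi)) ** (1.0 / 3.0)


def _region_sites(L: int, predicate) -> np.ndarray:
    ax = np.arange(L)
    xs, ys, zs = np.meshgrid(ax, ax, ax, indexing="ij")
    sites = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
    keep = np.array([predicate(x, y, z) for x, y, z in sites])
    return sites[keep]


def _pack_chains(
    L: int,
    groups: Sequence[tuple[int, int, object]],
    rng: np.random.Generator,
    n_restarts: int = 30,
) -> list[list[tuple[int, int, int]]]:
    """Grow chains group by group; each group = (n_chains, length, allowed)."""
    site_cache = [_region_sites(L, allowed) for _, _, allowed in groups]
    for _ in range(n_restarts):
        occ = np.full((L, L, L), -1, dtype=np.int64)
        chains: list[list[tuple[int, int, int]]] = []
        ok = True
        for (n_chains, length, allowed), sites in zip(groups, site_cache):
            for _c in range(n_chains):
                path = None
                for _retry in range(80):
                    path = _grow_chain(occ, length, allowed, sites, rng,
                                       max_backtrack=500)
                    if path is not None:
                        break
                if path is None:
                    ok = False
                    break
                chains.append(path)
            if not ok:
                break
        if ok:
            return chains
    raise SeedingError("droplet packing failed; lower the target density")


def _default_table(codes: Sequence[str], energy: float = -3.3) -> InteractionTable:
    return InteractionTable.uniform(tuple(codes), energy)


def make_random_mixed_condensate(
    n_per_species: Sequence[int],
    chain_length: int,
    L: int,
    seed: int,
    phi: float = 0.6,
    table: InteractionTable | None = None,
) -> tuple[LatticeState, dict]:
    """Dense droplet with species labels assigned at random to chain slots.

    All chains are grown identically inside one ball, then species labels
    are distributed uniformly at random over chain slots, so the generative
    ground truth is random mixing: E[L_i-j] = 1 for every pair.
    """
    rng = np.random.default_rng(seed)
    n_per_species = [int(n) for n in n_per_species]
    codes = [chr(ord("A") + i) for i in range(len(n_per_species))]
    active = [i for i, n in enumerate(n_per_species) if n > 0]
    n_chains = sum(n_per_species)
    n_beads = n_chains * chain_length
    radius = _ball_radius(n_beads, phi)
    c = L / 2.0

    def in_ball(x, y, z):
        return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2

    if n_beads > 4.2 * radius**3:  # sanity: ball volume must hold the beads
        raise SeedingError("ball too small for bead count")
    paths = _pack_chains(L, [(n_chains, chain_length, in_ball)], rng)
    # random assignment of grown paths to species-grouped chain slots
    order = rng.permutation(n_chains)
    paths = [paths[i] for i in order]
    species = tuple(
        ChainSpec.homopolymer(codes[i], codes[i], chain_length) for i in active
    )
    counts = tuple(n_per_species[i] for i in active)
    if table is None:
        table = _default_table([codes[i] for i in active])
    system = System(species, counts, table, L)
    positions = np.array([s for p in paths for s in p], dtype=np.int64)
    state = LatticeState(
        system=system,
        positions=positions,
        partner=np.full(system.n_beads, -1, dtype=np.int64),
        temperature=1.0,
    )
    state.validate()
    truth = {
        "kind": "random_mixed_condensate",
        "expected_L": 1.0,
        "radius": radius,
        "phi": phi,
        "seed": seed,
    }
    return state, truth


def make_core_shell_condensate(
    n_core: int,
    n_shell: int,
    chain_length: int,
    L: int,
    seed: int,
    phi: float = 0.6,
    table: InteractionTable | None = None,
) -> tuple[LatticeState, dict]:
    """Core-shell droplet: species A packed in an inner ball, B around it.

    The construction enriches homotypic contacts, so the ground truth is
    L_A-A > 1 and L_B-B > 1 (internally demixed condensate), and species
    A's radial density sits inside species B's.
    """
    rng = np.random.default_rng(seed)
    core_beads = n_core * chain_length
    total_beads = (n_core + n_shell) * chain_length
    r_core = _ball_radius(core_beads, phi)
    r_outer = max(_ball_radius(total_beads, phi), r_core + 2.5)
    c = L / 2.0

    def radius2(x, y, z):
        return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2

    def in_core(x, y, z):
        return radius2(x, y, z) <= r_core**2

    def in_shell(x, y, z):
        return r_core**2 < radius2(x, y, z) <= r_outer**2

    groups = []
    if n_core > 0:
        groups.append((n_core, chain_length, in_core))
    if n_shell > 0:
        groups.append((n_shell, chain_length, in_shell))
    paths = _pack_chains(L, groups, rng)
    species = []
    counts = []
    if n_core > 0:
        species.append(ChainSpec.homopolymer("A", "A", chain_length))
        counts.append(n_core)
    if n_shell > 0:
        species.append(ChainSpec.homopolymer("B", "B", chain_length))
        counts.append(n_shell)
    if table is None:
        table = _default_table([s.residues[0] for s in species])
    system = System(tuple(species), tuple(counts), table, L)
    positions = np.array([s for p in paths for s in p], dtype=np.int64)
    state = LatticeState(
        system=system,
        positions=positions,
        partner=np.full(system.n_beads, -1, dtype=np.int64),
        temperature=1.0,
    )
    state.validate()
    truth = {
        "kind": "core_shell_condensate",
        "expected": "L_A-A > 1 and L_B-B > 1",
        "r_core": r_core,
        "r_outer": r_outer,
        "seed": seed,
    }
    return state, truth


# ---------------------------------------------------------------------------
# analytic fixtures
# ---------------------------------------------------------------------------

def make_logistic_profile(
    rho_dense: float,
    rho_dilute: float,
    r0: float,
    w: float,
    n_shells: int = 160,
    noise_sigma: float = 0.0,
    seed: int = 0,
    species: str = "synthetic",
) -> tuple[RadialProfile, dict]:
    """Radial profile generated from the logistic closed form plus noise."""
    rng = np.random.default_rng(seed)
    edges = np.arange(n_shells + 1) * SHELL_WIDTH
    centers = 0.5 * (edges[:-1] + edges[1:])
    rho = logistic(centers, rho_dense, rho_dilute, r0, w)
    if noise_sigma > 0:
        rho = rho + rng.normal(0.0, noise_sigma, size=rho.shape)
    site_counts = np.full(n_shells, 10**6, dtype=np.int64)
    profile = RadialProfile(
        edges=edges,
        site_counts=site_counts,
        bead_counts={species: rho * site_counts},
        L=int(2 * edges[-1]),
        center=np.zeros(3),
    )
    truth = {
        "rho_dense": rho_dense,
        "rho_dilute": rho_dilute,
        "r0": r0,
        "w": w,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }
    return profile, truth


def make_leverrule_table(
    phase_dilute: tuple[float, float],
    phase_dense: tuple[float, float],
    fractions: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Tie-line table with totals placed by the lever rule.

    Each fraction f puts the total composition at
    (1-f)*phase_dilute + f*phase_dense; Gaussian noise of width
    ``noise_sigma`` is added to the measured dilute/dense compositions.
    Returns (DataFrame in the tie-line table format, ground truth dict with
    the generative slope).
    """
    import pandas as pd

    a = np.asarray(phase_dilute, dtype=float)
    b = np.asarray(phase_dense, dtype=float)
    if np.allclose(a, b):
        raise ValueError("phases must be distinct")
    rng = np.random.default_rng(seed)
    rows = []
    for mi, f in enumerate(fractions):
        tot = (1 - f) * a + f * b
        dil = a + rng.normal(0, noise_sigma, 2) if noise_sigma else a.copy()
        den = b + rng.normal(0, noise_sigma, 2) if noise_sigma else b.copy()
        for phase, point in (("dilute", dil), ("total", tot), ("dense", den)):
            rows.append(
                {
                    "mixture_id": f"mix{mi}",
                    "ratio": float(f),
                    "phase": phase,
                    "c_A": float(point[0]),
                    "c_B": float(point[1]),
                    "err_A": noise_sigma,
                    "err_B": noise_sigma,
                }
            )
    slope = (b[1] - a[1]) / (b[0] - a[0])
    truth = {"slope": float(slope), "phase_dilute": tuple(a),
             "phase_dense": tuple(b), "noise_sigma": noise_sigma, "seed": seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# synthetic PLCD-proxy sequences
# ---------------------------------------------------------------------------

def synthetic_plcd_sequence(
    length: int, n_pos: int, n_neg: int, seed: int = 0
) -> str:
    """Synthetic sequence with PLCD-like composition (not a real protein).

    Roughly 55% polar (G/S/T/N/Q), 12% aromatic (Y/F), 10% proline and a
    prescribed number of cationic (R/K) and anionic (D/E) residues, the
    remainder glycine; shuffled deterministically by seed.  Useful as a
    stand-in where real prion-like low-complexity domain sequences are a
    runtime input.
    """
    if n_pos + n_neg > length:
        raise ValueError("charged residues exceed sequence length")
    n_aromatic = int(round(0.12 * length))
    n_pro = int(round(0.10 * length))
    n_rest = length - n_pos - n_neg - n_aromatic - n_pro
    if n_rest < 0:
        raise ValueError("composition does not fit the sequence length")
    rng = np.random.default_rng(seed)
    pool = (
        list("RK" * ((n_pos + 1) // 2))[:n_pos]
        + list("DE" * ((n_neg + 1) // 2))[:n_neg]
        + [("Y" if i % 3 else "F") for i in range(n_aromatic)]
        + ["P"] * n_pro
        + [str(np.array(list("GSNQT"))[i % 5]) for i in range(n_rest)]
    )
    rng.shuffle(pool)
    return "".join(pool)


# ---------------------------------------------------------------------------
# preset systems
# ---------------------------------------------------------------------------

#: species-pair energy matrices from the homopolymer scenario suite
_TABLE_PRESETS: dict[str, dict[tuple[str, str], float]] = {
    "fig8a": {("A", "A"): -3.3, ("A", "B"): -3.3, ("B", "B"): -3.3},
    "fig8b": {("A", "A"): -3.0, ("A", "B"): -3.6, ("B", "B"): -3.0},
    "fig8c": {("A", "A"): -3.6, ("A", "B"): -3.0, ("B", "B"): -3.6},
    "fig8d": {("A", "A"): -3.0, ("A", "B"): -3.6, ("B", "B"): -3.6},
    "fig9a": {("A", "A"): -3.3, ("A", "B"): -3.3, ("B", "B"): -3.3},
    "fig9b": {("A", "A"): -3.6, ("A", "B"): -3.45, ("B", "B"): -3.3},
    "fig9c": {
        ("A", "A"): -3.3, ("A", "B"): -3.3, ("A", "C"): -3.3,
        ("B", "B"): -3.3, ("B", "C"): -3.3, ("C", "C"): -3.3,
    },
}


def interaction_table_preset(name: str) -> InteractionTable:
    """Species-level homopolymer energy presets (A = first species, etc.)."""
    if name not in _TABLE_PRESETS:
        raise KeyError(
            f"unknown table preset {name!r}; available: "
            f"{sorted(_TABLE_PRESETS)}"
        )
    return InteractionTable.from_species_energies(_TABLE_PRESETS[name])


PRESET_NAMES = (
    "fig8a", "fig8b", "fig8c", "fig8d",
    "fig9a", "fig9b", "fig9c",
    "pseudo_binary_A1", "fus_a1_mix",
)

# Desk-scale overrides: production systems use 150^3 (homopolymers) or
# 120^3 (sequence mixtures) lattices and 3e10 steps; presets ship with
# small lattices and step counts runnable on one CPU, flagged scaled_down.
_DESK_L_HOMO = 48
_DESK_L_SEQ = 44
_DESK_STEPS = 4_000_000


def _homopolymer_preset(
    name: str,
    lengths: Sequence[int],
    ratios: Sequence[float],
    temperatures: Sequence[float],
    L: int = _DESK_L_HOMO,
) -> SimulationConfig:
    table = interaction_table_preset(name)
    counts = select_chain_counts(ratios, lengths, L, target_phi=0.016)
    codes = [chr(ord("A") + i) for i in range(len(lengths))]
    species = tuple(
        ChainSpec.homopolymer(f"H{n}" if len(set(lengths)) > 1 else code,
                              code, n)
        for code, n in zip(codes, lengths)
    )
    return SimulationConfig(
        lattice_size=L,
        species=species,
        chain_counts=counts,
        table=table,
        temperatures=tuple(temperatures),
        total_steps=_DESK_STEPS,
        seed_box=min(35, L // 2),
        scaled_down=True,
        name=name,
    )


def preset_system(name: str, seed: int = 0) -> SimulationConfig:
    """Preset simulation configurations for the scenario suite.

    Energies, lengths and stoichiometries follow the scenario definitions;
    lattice sizes and step counts are desk-scale overrides (flagged by
    ``scaled_down=True``).  Sequence presets use synthetic PLCD-proxy
    sequences, since real PLCD sequences and their bespoke energy table are
    runtime inputs.
    """
    if name in ("fig8a", "fig8b", "fig8c", "fig8d"):
        cfg = _homopolymer_preset(
            name, lengths=(150, 150), ratios=(0.5, 0.5),
            temperatures=(50.0, 54.0),
        )
    elif name == "fig9a":
        # equal mass concentration of H150 and H300 -> equal bead counts
        cfg = _homopolymer_preset(
            name, lengths=(150, 300), ratios=(2 / 3, 1 / 3),
            temperatures=(55.0,),
        )
    elif name == "fig9b":
        cfg = _homopolymer_preset(
            name, lengths=(150, 300), ratios=(2 / 3, 1 / 3),
            temperatures=(56.0,),
        )
    elif name == "fig9c":
        # equal mass of H200/H300/H400 -> molecule ratio 6:4:3
        cfg = _homopolymer_preset(
            name, lengths=(200, 300, 400), ratios=(6 / 13, 4 / 13, 3 / 13),
            temperatures=(57.0,), L=64,
        )
    elif name == "pseudo_binary_A1":
        seq = synthetic_plcd_sequence(135, n_pos=7, n_neg=3, seed=11)
        spec_a = ChainSpec.from_sequence("A1proxy_A", seq)
        spec_b = ChainSpec.from_sequence("A1proxy_B", seq)
        table = InteractionTable.uniform(
            tuple(sorted(set(seq))), -3.3, lambda_el=0.0
        )
        counts = select_chain_counts(
            (0.5, 0.5), (135, 135), _DESK_L_SEQ, target_phi=0.016
        )
        cfg = SimulationConfig(
            lattice_size=_DESK_L_SEQ,
            species=(spec_a, spec_b),
            chain_counts=counts,
            table=table,
            temperatures=(50.0,),
            total_steps=_DESK_STEPS,
            seed_box=min(35, _DESK_L_SEQ // 2),
            scaled_down=True,
            name=name,
        )
    elif name == "fus_a1_mix":
        fus = ChainSpec.from_sequence(
            "FUSproxy", synthetic_plcd_sequence(214, n_pos=2, n_neg=6, seed=21)
        )
        a1 = ChainSpec.from_sequence(
            "A1proxy", synthetic_plcd_sequence(135, n_pos=7, n_neg=3, seed=11)
        )
        alphabet = tuple(sorted(set(fus.residues) | set(a1.residues)))
        table = InteractionTable.uniform(alphabet, -3.3, lambda_el=100.0)
        counts = select_chain_counts(
            (0.5, 0.5), (214, 135), _DESK_L_SEQ, target_phi=0.016
        )
        cfg = SimulationConfig(
            lattice_size=_DESK_L_SEQ,
            species=(fus, a1),
            chain_counts=counts,
            table=table,
            temperatures=(50.0,),
            total_steps=_DESK_STEPS,
            seed_box=min(35, _DESK_L_SEQ // 2),
            scaled_down=True,
            name=name,
        )
    else:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESET_NAMES)}"
        )
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# declarative fixture spec
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Declarative fixture request: kind + parameters + seed.

    ``make()`` dispatches to the matching generator and returns
    (artifact, ground_truth).
    """

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    _KINDS = (
        "random_mixed_condensate",
        "core_shell_condensate",
        "logistic_profile",
        "leverrule_table",
        "pseudo_binary_system",
        "homopolymer_preset",
    )

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")

    def make(self):
        p = dict(self.params)
        if self.kind == "random_mixed_condensate":
            return make_random_mixed_condensate(seed=self.seed, **p)
        if self.kind == "core_shell_condensate":
            return make_core_shell_condensate(seed=self.seed, **p)
        if self.kind == "logistic_profile":
            return make_logistic_profile(seed=self.seed, **p)
        if self.kind == "leverrule_table":
            return make_leverrule_table(seed=self.seed, **p)
        if self.kind == "pseudo_binary_system":
            return preset_system("pseudo_binary_A1", seed=self.seed), {}
        return preset_system(p.pop("name"), seed=self.seed), {}
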