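"""Shared fixtures: small Monte Carlo campaigns reused across tests.

Simulation fixtures are session-scoped because each run costs seconds to
minutes; tests must not mutate the returned trajectories.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixsep import (
    ChainSpec,
    InteractionTable,
    SimulationConfig,
    interaction_table_preset,
    run_simulation,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def run_homopolymer(
    species,
    counts,
    table,
    temperatures,
    seed,
    L=48,
    steps=8_000_000,
    seed_box=18,
    check=False,
):
    cfg = SimulationConfig(
        lattice_size=L,
        species=tuple(species),
        chain_counts=tuple(counts),
        table=table,
        temperatures=tuple(temperatures),
        total_steps=steps,
        seed_box=seed_box,
        seed=seed,
    )
    return run_simulation(cfg, check_invariants=check)


@pytest.fixture(scope="session")
def mers25():
    return (
        ChainSpec.homopolymer("A", "A", 25),
        ChainSpec.homopolymer("B", "B", 25),
    )


@pytest.fixture(scope="session")
def fig8a_runs(mers25):
    """Equal-interaction (-3.3) binary homopolymer mixture, 5 replicates at
    two temperatures in the scaled two-phase regime."""
    table = interaction_table_preset("fig8a")
    groups = {40.0: [], 44.0: []}
    for seed in range(1, 6):
        trs = run_homopolymer(mers25, (36, 36), table, (40.0, 44.0), seed)
        groups[40.0].append(trs[0])
        groups[44.0].append(trs[1])
    return groups


@pytest.fixture(scope="session")
def fig8_scenario_runs(mers25):
    """Hetero-strong / homo-strong / weak-A-A scenarios, 2 replicates each
    at a low two-phase temperature."""
    out = {}
    for name in ("fig8b", "fig8c", "fig8d"):
        table = interaction_table_preset(name)
        out[name] = [
            run_homopolymer(mers25, (36, 36), table, (40.0,), seed)[0]
            for seed in (1, 2)
        ]
    return out


@pytest.fixture(scope="session")
def pseudo_binary_runs(mers25):
    """One homopolymer species with half its chains relabeled: runs at
    molecule fractions a = 0 (all B), 0.5, and 1 (all A), 3 replicates."""
    A, B = mers25
    table = interaction_table_preset("fig8a")
    tabA = InteractionTable.uniform(("A",), -3.3)
    tabB = InteractionTable.uniform(("B",), -3.3)
    out = {}
    out[1.0] = [
        run_homopolymer((A,), (72,), tabA, (40.0,), seed)[0]
        for seed in (11, 12, 13)
    ]
    out[0.0] = [
        run_homopolymer((B,), (72,), tabB, (40.0,), seed)[0]
        for seed in (21, 22, 23)
    ]
    out[0.5] = [
        run_homopolymer((A, B), (36, 36), table, (40.0,), seed)[0]
        for seed in (31, 32, 33)
    ]
    return out


@pytest.fixture(scope="session")
def length_effect_singles():
    """Single-species H50 and H100 systems at equal contact energy and
    equal total bead count, 3 replicates each."""
    H50 = ChainSpec.homopolymer("H50", "A", 50)
    H100 = ChainSpec.homopolymer("H100", "B", 100)
    tabA = InteractionTable.uniform(("A",), -3.3)
    tabB = InteractionTable.uniform(("B",), -3.3)
    return {
        "H50": [
            run_homopolymer((H50,), (36,), tabA, (48.0,), seed)[0]
            for seed in (1, 2, 3)
        ],
        "H100": [
            run_homopolymer((H100,), (18,), tabB, (48.0,), seed)[0]
            for seed in (1, 2, 3)
        ],
    }


@pytest.fixture(scope="session")
def length_effect_mixture():
    """Equal-mass H50/H100 mixture near the composite two-phase boundary."""
    H50 = ChainSpec.homopolymer("H50", "A", 50)
    H100 = ChainSpec.homopolymer("H100", "B", 100)
    table = InteractionTable.from_species_energies(
        {("A", "A"): -3.3, ("A", "B"): -3.3, ("B", "B"): -3.3}
    )
    return [
        run_homopolymer(
            (H50, H100), (36, 18), table, (50.0,), seed,
            L=56, steps=12_000_000, seed_box=22,
        )[0]
        for seed in (1, 2)
    ]
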