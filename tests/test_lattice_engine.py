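"""Engine correctness: geometry invariants, energetics, sampling."""

import itertools
import math

import numpy as np
import pytest

from mixsep import (
    ChainSpec,
    InteractionTable,
    SeedingError,
    SimulationConfig,
    acceptance_probability,
    init_dense_seed,
    metropolis_step,
    run_simulation,
    select_chain_counts,
    total_energy,
)
from mixsep.lattice_engine import LocalMove, System, LatticeState, run_mc


def uniform_system(n_chains=2, length=3, L=12, iso=-1.0, lambda_el=0.0):
    spec = ChainSpec.homopolymer("A", "A", length)
    table = InteractionTable.uniform(("A",), iso, lambda_el=lambda_el)
    return System((spec,), (n_chains,), table, L)


class TestSelectChainCounts:
    def test_plcd_mixture_on_production_lattice(self):
        # 1:1 of 214-mer and 135-mer on 120^3 targeting 0.016:
        # exhaustive search gives 79 pairs, phi = 27571/1728000
        counts = select_chain_counts((0.5, 0.5), (214, 135), 120, 0.016)
        assert counts == (79, 79)
        phi = (79 * 214 + 79 * 135) / 120**3
        assert phi == pytest.approx(27571 / 1728000)

    def test_exact_fraction_attainable(self):
        assert select_chain_counts((1.0,), (1,), 10, 0.5) == (500,)

    def test_degenerate_ratio_reduces_to_single_species(self):
        counts = select_chain_counts((1.0, 0.0), (25, 50), 20, 0.1)
        assert counts[1] == 0
        assert counts[0] * 25 / 20**3 == pytest.approx(0.1)

    def test_matches_exhaustive_search(self):
        L, lengths = 16, (7, 3)
        counts = select_chain_counts((0.5, 0.5), lengths, L, 0.05)
        unit = sum(lengths)
        best = min(
            range(1, 60), key=lambda m: abs(m * unit / L**3 - 0.05)
        )
        assert counts == (best, best)

    def test_unit_too_large_raises(self):
        with pytest.raises(ValueError):
            select_chain_counts((1.0,), (200,), 4, 0.2)


class TestDenseSeed:
    def test_two_bead_chain_in_tiny_subbox(self):
        spec = ChainSpec.homopolymer("A", "A", 2)
        table = InteractionTable.uniform(("A",), 0.0)
        cfg = SimulationConfig(
            lattice_size=8, species=(spec,), chain_counts=(1,),
            table=table, temperatures=(1.0,), total_steps=10, seed_box=2,
        )
        state = init_dense_seed(cfg, np.random.default_rng(0))
        state.validate()
        d = np.abs(state.positions[0] - state.positions[1])
        assert (d <= 1).all() and d.sum() > 0
        lo, hi = (8 - 2) // 2, (8 - 2) // 2 + 2
        assert ((state.positions >= lo) & (state.positions < hi)).all()

    def test_capacity_error(self):
        spec = ChainSpec.homopolymer("A", "A", 30)
        table = InteractionTable.uniform(("A",), 0.0)
        cfg = SimulationConfig(
            lattice_size=10, species=(spec,), chain_counts=(1,),
            table=table, temperatures=(1.0,), total_steps=10, seed_box=3,
        )
        with pytest.raises(SeedingError):
            init_dense_seed(cfg, np.random.default_rng(0))

    def test_many_chains_fit_when_capacity_allows(self):
        # 2 x 8 chains of 25 beads = 400 beads in a 10^3 sub-box
        A = ChainSpec.homopolymer("A", "A", 25)
        B = ChainSpec.homopolymer("B", "B", 25)
        table = InteractionTable.uniform(("A", "B"), -1.0)
        cfg = SimulationConfig(
            lattice_size=24, species=(A, B), chain_counts=(8, 8),
            table=table, temperatures=(10.0,), total_steps=10, seed_box=10,
        )
        state = init_dense_seed(cfg, np.random.default_rng(1))
        state.validate()
        assert state.positions.shape == (400, 3)


class TestMetropolis:
    def test_acceptance_probability_closed_forms(self):
        assert acceptance_probability(0.0, 3.0) == 1.0
        assert acceptance_probability(-5.0, 3.0) == 1.0
        assert acceptance_probability(3.0, 3.0) == pytest.approx(math.exp(-1))
        assert acceptance_probability(1.0, 1e12) == pytest.approx(1.0)

    def test_single_step_updates_energy_consistently(self):
        system = uniform_system(n_chains=3, length=4, L=10)
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(
            lattice_size=10, species=system.species, chain_counts=system.counts,
            table=system.table, temperatures=(2.0,), total_steps=10, seed_box=6,
        )
        state = init_dense_seed(cfg, rng, temperature=2.0)
        offs = [
            o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)
        ]
        accepted = 0
        for i in range(300):
            move = LocalMove(
                bead=int(rng.integers(state.system.n_beads)),
                offset=offs[int(rng.integers(26))],
            )
            accepted += metropolis_step(state, move, rng)
        assert accepted > 0
        assert state.total_energy == pytest.approx(
            total_energy(state), abs=1e-9
        )
        state.validate()

    def test_rejected_geometry_leaves_state_unchanged(self):
        system = uniform_system(n_chains=1, length=2, L=6)
        positions = np.array([[0, 0, 0], [0, 0, 1]], dtype=np.int64)
        state = LatticeState(
            system=system, positions=positions,
            partner=np.full(2, -1, dtype=np.int64), temperature=1.0,
        )
        before = state.positions.copy()
        # move bead 0 onto bead 1: excluded volume, must reject
        ok = metropolis_step(state, LocalMove(0, (0, 0, 1)),
                             np.random.default_rng(0))
        assert not ok
        np.testing.assert_array_equal(state.positions, before)


class TestTotalEnergy:
    def test_isolated_beads_zero(self):
        spec = ChainSpec.homopolymer("A", "A", 1)
        table = InteractionTable.uniform(("A",), -3.3)
        system = System((spec,), (2,), table, 12)
        positions = np.array([[0, 0, 0], [6, 6, 6]], dtype=np.int64)
        st = LatticeState(system=system, positions=positions,
                          partner=np.full(2, -1, np.int64), temperature=1.0)
        assert st.total_energy == 0.0

    def test_adjacent_beads_contact_energy(self):
        spec = ChainSpec.homopolymer("A", "A", 1)
        table = InteractionTable.uniform(("A",), -3.3)
        system = System((spec,), (2,), table, 12)
        positions = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int64)
        st = LatticeState(system=system, positions=positions,
                          partner=np.full(2, -1, np.int64), temperature=1.0)
        assert st.total_energy == pytest.approx(-3.3)

    def test_bonded_neighbors_excluded(self):
        system = uniform_system(n_chains=1, length=2, L=12, iso=-3.3)
        positions = np.array([[0, 0, 0], [0, 0, 1]], dtype=np.int64)
        st = LatticeState(system=system, positions=positions,
                          partner=np.full(2, -1, np.int64), temperature=1.0)
        assert st.total_energy == 0.0

    def test_electrostatic_term_enters_contacts(self):
        a = ChainSpec.homopolymer("A", "A", 1, ncpr=0.2, fcr=0.2)
        table = InteractionTable.uniform(("A",), -1.0, lambda_el=10.0)
        system = System((a,), (2,), table, 12)
        positions = np.array([[0, 0, 0], [0, 1, 0]], dtype=np.int64)
        st = LatticeState(system=system, positions=positions,
                          partner=np.full(2, -1, np.int64), temperature=1.0)
        assert st.total_energy == pytest.approx(-1.0 + 10 * 0.2**2)


class TestRunSimulation:
    def make_cfg(self, seed=3, steps=150_000):
        A = ChainSpec.homopolymer("A", "A", 8)
        B = ChainSpec.homopolymer("B", "B", 8)
        table = InteractionTable.uniform(("A", "B"), -2.0, aniso_energy=-0.7)
        return SimulationConfig(
            lattice_size=16, species=(A, B), chain_counts=(4, 4),
            table=table, temperatures=(6.0,), total_steps=steps,
            seed_box=8, seed=seed,
        )

    def test_same_seed_reproduces_bit_for_bit(self):
        t1 = run_simulation(self.make_cfg())[0]
        t2 = run_simulation(self.make_cfg())[0]
        assert len(t1.frames) == len(t2.frames)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1.positions, f2.positions)
            np.testing.assert_array_equal(f1.partner, f2.partner)
            assert f1.energy == f2.energy

    def test_different_seed_differs(self):
        t1 = run_simulation(self.make_cfg(seed=3))[0]
        t2 = run_simulation(self.make_cfg(seed=4))[0]
        assert any(
            (f1.positions != f2.positions).any()
            for f1, f2 in zip(t1.frames, t2.frames)
        )

    def test_bead_count_conserved_and_invariants_hold(self):
        traj = run_simulation(self.make_cfg())[0]
        n = traj.system.n_beads
        for i in range(len(traj.frames)):
            assert traj.frames[i].positions.shape == (n, 3)
            traj.state_at(i).validate()  # includes energy bookkeeping

    def test_snapshots_start_after_analysis_start(self):
        cfg = self.make_cfg()
        traj = run_simulation(cfg)[0]
        assert traj.frames[0].step == cfg.analysis_start
        assert traj.frames[-1].step == cfg.total_steps

    def test_tsv_round_trip(self, tmp_path):
        traj = run_simulation(self.make_cfg())[0]
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        back = traj.from_tsv(path)
        assert back.temperature == traj.temperature
        assert back.system.n_beads == traj.system.n_beads
        assert back.system.species_names == traj.system.species_names
        for f1, f2 in zip(traj.frames, back.frames):
            np.testing.assert_array_equal(f1.positions, f2.positions)
            np.testing.assert_array_equal(f1.partner, f2.partner)
            assert f2.energy == pytest.approx(f1.energy)


def enumerate_dimer_contact_probability(L, iso, T):
    """Exact Boltzmann contact probability for two monomers on an L^3
    periodic lattice: 26 contact offsets weighted exp(-iso/T), the other
    L^3 - 27 relative offsets weighted 1."""
    w_contact = 26 * math.exp(-iso / T)
    w_free = L**3 - 27
    return w_contact / (w_contact + w_free)


def test_two_bead_boltzmann_frequencies_match_enumeration():
    """Long-run contact frequency of two monomers matches the exact
    Boltzmann weight within Monte Carlo error (detailed balance check)."""
    L, iso, T = 6, -1.0, 1.0
    spec = ChainSpec.homopolymer("A", "A", 1)
    table = InteractionTable.uniform(("A",), iso)
    system = System((spec,), (2,), table, L)
    positions = np.array([[0, 0, 0], [3, 3, 3]], dtype=np.int64)
    state = LatticeState(system=system, positions=positions,
                         partner=np.full(2, -1, np.int64), temperature=T)
    p_exact = enumerate_dimer_contact_probability(L, iso, T)
    hits, n_samples = 0, 3000
    for i in range(n_samples):
        run_mc(state, 2000, seed=100 + i)
        d = (state.positions[0] - state.positions[1]) % L
        d = np.where(d > L // 2, d - L, d)
        if (np.abs(d) <= 1).all() and np.abs(d).sum() > 0:
            hits += 1
    p_hat = hits / n_samples
    se = math.sqrt(p_exact * (1 - p_exact) / n_samples)
    assert abs(p_hat - p_exact) < 4 * se


def enumerate_trimer_mean_rg2():
    """Brute-force mean squared Rg over all self-avoiding 3-bead
    conformations with 26-neighborhood bonds (no interactions)."""
    offs = [
        np.array(o) for o in itertools.product((-1, 0, 1), repeat=3) if any(o)
    ]
    vals = []
    for o1 in offs:
        for o2 in offs:
            p = np.array([[0, 0, 0], o1, o1 + o2])
            if (p[2] == p[0]).all():
                continue  # excluded volume
            com = p.mean(axis=0)
            vals.append(((p - com) ** 2).sum(axis=1).mean())
    return float(np.mean(vals))


def test_single_chain_rg_matches_enumeration():
    """An isolated athermal 3-mer samples conformations whose mean Rg^2
    matches exhaustive enumeration."""
    from mixsep.condensate_geometry import unwrap_chain

    spec = ChainSpec.homopolymer("A", "A", 3)
    table = InteractionTable.uniform(("A",), 0.0)
    cfg = SimulationConfig(
        lattice_size=10, species=(spec,), chain_counts=(1,), table=table,
        temperatures=(1.0,), total_steps=2_000_000, snapshot_interval=20_000,
        seed_box=4, seed=7,
    )
    traj = run_simulation(cfg, check_invariants=False)[0]
    rg2 = []
    for fr in traj.frames:
        u = unwrap_chain(fr.positions, 10).astype(float)
        rg2.append(((u - u.mean(axis=0)) ** 2).sum(axis=1).mean())
    expected = enumerate_trimer_mean_rg2()
    assert np.mean(rg2) == pytest.approx(expected, rel=0.05)


def test_athermal_limit_geometry_independent_of_interaction_table():
    """At T -> infinity the sampled geometry is an athermal self-avoiding
    ensemble: mean contacts per bead must not depend on the energy table."""
    means = []
    for iso in (0.0, -3.3):
        A = ChainSpec.homopolymer("A", "A", 10)
        table = InteractionTable.uniform(("A",), iso)
        cfg = SimulationConfig(
            lattice_size=14, species=(A,), chain_counts=(6,), table=table,
            temperatures=(1e9,), total_steps=2_000_000,
            snapshot_interval=100_000, seed_box=8, seed=9,
        )
        traj = run_simulation(cfg, check_invariants=False)[0]
        contacts = []
        for i in range(len(traj.frames)):
            st = traj.state_at(i)
            # nonbonded contact count = energy / iso when iso != 0
            e = total_energy(st)
            contacts.append(e / iso if iso else np.nan)
        if iso:
            means.append(np.mean(contacts))
        else:
            ref_traj = traj
    # compare contact statistics of the athermal run computed with the
    # attractive table against the attractive run's own statistics
    probe = InteractionTable.uniform(("A",), -3.3)
    ref = []
    for i in range(len(ref_traj.frames)):
        st = ref_traj.state_at(i)
        ref.append(total_energy(st, table=probe) / -3.3)
    a, b = np.mean(ref), means[0]
    pooled = np.std(ref, ddof=1) + 1e-9
    assert abs(a - b) < 4 * pooled
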