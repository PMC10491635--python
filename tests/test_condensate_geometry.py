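"""Condensate identification, shell priors, interface fits, Rg profiles."""

import itertools
import math

import numpy as np
import pytest

from mixsep import (
    ChainSpec,
    InteractionTable,
    find_condensate,
    fit_logistic,
    make_logistic_profile,
    mean_profile,
    phase_concentrations,
    radial_density,
    rg_profile,
)
from mixsep.condensate_geometry import (
    LN9,
    chain_rg,
    periodic_center,
    unwrap_chain,
)
from mixsep.lattice_engine import LatticeState, System


def build_state(chains, L=20, species_per_chain=None, codes=("A", "B")):
    """Assemble a LatticeState from explicit chain coordinate lists."""
    lengths = [len(c) for c in chains]
    if species_per_chain is None:
        species_per_chain = [0] * len(chains)
    order = np.argsort(species_per_chain, kind="stable")
    chains = [chains[i] for i in order]
    species_per_chain = [species_per_chain[i] for i in order]
    used = sorted(set(species_per_chain))
    specs, counts = [], []
    for s in used:
        chains_s = [c for c, sp in zip(chains, species_per_chain) if sp == s]
        if len({len(c) for c in chains_s}) != 1:
            raise ValueError("one length per species in this helper")
        specs.append(
            ChainSpec.homopolymer(codes[s], codes[s], len(chains_s[0]))
        )
        counts.append(len(chains_s))
    table = InteractionTable.uniform(tuple(codes[s] for s in used), -1.0)
    system = System(tuple(specs), tuple(counts), table, L)
    positions = np.array(
        [site for chain in chains for site in chain], dtype=np.int64
    )
    return LatticeState(
        system=system, positions=positions,
        partner=np.full(len(positions), -1, np.int64), temperature=1.0,
    )


class TestFindCondensate:
    def test_all_chains_contacting_form_one_component(self):
        chains = [
            [(5, 5, 5), (5, 5, 6)],
            [(6, 5, 5), (6, 5, 6)],
            [(7, 5, 5), (7, 5, 6)],
        ]
        st = build_state(chains)
        cond = find_condensate(st)
        assert cond.chains == (0, 1, 2)
        assert cond.is_condensate

    def test_largest_component_wins(self):
        big = [
            [(5 + i, 5, 5), (5 + i, 5, 6)] for i in range(4)
        ]
        small = [[(15, 15, 15), (15, 15, 16)], [(16, 15, 15), (16, 15, 16)]]
        st = build_state(big + small)
        cond = find_condensate(st)
        assert len(cond.chains) == 4
        assert set(cond.chains) == {0, 1, 2, 3}

    def test_dispersed_system_flagged(self):
        chains = [
            [(0, 0, 0), (0, 0, 1)],
            [(6, 6, 6), (6, 6, 7)],
            [(12, 12, 12), (12, 12, 13)],
        ]
        st = build_state(chains)
        cond = find_condensate(st, min_fraction=0.5)
        assert not cond.is_condensate
        assert len(cond.chains) == 1

    def test_wrapped_cluster_centroid_inside_cluster(self):
        """A cluster straddling the periodic boundary has its centroid at
        the boundary, not at the box center."""
        L = 20
        chains = [
            [(19, 10, 10), (19, 10, 11)],
            [(0, 10, 10), (0, 10, 11)],
            [(18, 10, 10), (18, 10, 11)],
        ]
        st = build_state(chains, L=L)
        cond = find_condensate(st)
        cx = cond.center[0]
        assert min(cx, L - cx) < 2.0  # near x = 0 wrap, far from x = 10

    def test_periodic_center_matches_minimum_image_mean(self):
        L = 16
        pts = np.array([[15, 8, 8], [0, 8, 8], [1, 8, 8]])
        c = periodic_center(pts, L)
        assert min(c[0], L - c[0]) == pytest.approx(0.0, abs=0.2)
        assert c[1] == pytest.approx(8.0, abs=1e-9)


class TestRadialDensity:
    def test_shell_site_counts_sum_to_box(self):
        st = build_state([[(5, 5, 5), (5, 5, 6)]], L=12)
        prof = radial_density(st, np.array([5.0, 5.0, 5.0]))
        assert prof.site_counts.sum() == 12**3

    def test_empty_shells_zero_and_beads_in_exact_shells(self):
        """Hand-built beads at known distances appear only in the shells
        covering those exact distances."""
        L = 16
        center = np.array([8.0, 8.0, 8.0])
        chains = [[(8, 8, 8), (8, 8, 9)], [(8, 8, 11), (8, 9, 11)]]
        st = build_state(chains, L=L)
        prof = radial_density(st, center)
        dists = [0.0, 1.0, 3.0, math.sqrt(10)]
        expect = {int(d / 0.25) for d in dists}
        nonzero = set(np.nonzero(prof.density("A") > 0)[0])
        assert nonzero == expect

    def test_uniform_occupancy_gives_flat_profile(self):
        L = 16
        rng = np.random.default_rng(0)
        flat = rng.choice(L**3, size=400, replace=False)
        sites = np.stack(np.unravel_index(flat, (L, L, L)), axis=1)
        chains = [[tuple(s)] for s in sites]
        st = build_state(chains, L=L)
        prof = radial_density(st, np.array([7.3, 8.1, 7.9]))
        d = prof.density("A")
        big = prof.site_counts > 200
        phi = 400 / L**3
        assert np.nanmax(np.abs(d[big] - phi)) < 6 * math.sqrt(
            phi / 200
        )

    def test_species_profiles_sum_to_total(self):
        chains = [[(5, 5, 5), (5, 5, 6)], [(6, 6, 6), (6, 6, 7)]]
        st = build_state(chains, species_per_chain=[0, 1])
        prof = radial_density(st, np.array([5.5, 5.5, 5.5]))
        np.testing.assert_allclose(
            np.nan_to_num(prof.density("A") + prof.density("B")),
            np.nan_to_num(prof.density()),
        )


class TestLogisticFit:
    def test_noiseless_recovery_to_1e_minus_6(self):
        truth = dict(rho_dense=0.3, rho_dilute=0.001, r0=20.0, w=2.0)
        prof, _ = make_logistic_profile(**truth, n_shells=160)
        fit = fit_logistic(prof, species="synthetic")
        assert not fit.flagged
        assert fit.rho_dense == pytest.approx(truth["rho_dense"], abs=1e-6)
        assert fit.rho_dilute == pytest.approx(truth["rho_dilute"], abs=1e-6)
        assert fit.r0 == pytest.approx(truth["r0"], abs=1e-6)
        assert fit.w == pytest.approx(truth["w"], abs=1e-6)

    def test_noisy_recovery_within_5_percent(self):
        truth = dict(rho_dense=0.3, rho_dilute=0.001, r0=20.0, w=2.0)
        r0s, ws, dens = [], [], []
        for seed in range(50):
            prof, _ = make_logistic_profile(
                **truth, n_shells=160, noise_sigma=0.01, seed=seed
            )
            fit = fit_logistic(prof, species="synthetic")
            assert not fit.flagged
            r0s.append(fit.r0)
            ws.append(fit.w)
            dens.append(fit.rho_dense)
        assert np.mean(r0s) == pytest.approx(truth["r0"], rel=0.05)
        assert np.mean(ws) == pytest.approx(truth["w"], rel=0.05)
        assert np.mean(dens) == pytest.approx(truth["rho_dense"], rel=0.05)

    def test_constant_profile_flagged_degenerate(self):
        prof, _ = make_logistic_profile(0.2, 0.2, 10.0, 1.0, n_shells=60)
        fit = fit_logistic(prof, species="synthetic")
        assert fit.flagged
        assert "flat" in fit.message

    def test_interface_band_is_10_90_band(self):
        prof, _ = make_logistic_profile(0.3, 0.0, 20.0, 2.0, n_shells=160)
        fit = fit_logistic(prof, species="synthetic")
        assert fit.interface_hi - fit.interface_lo == pytest.approx(
            2 * fit.w * LN9
        )
        # logistic evaluates to 10% / 90% of the span at the band edges
        from mixsep.condensate_geometry import logistic

        lo_val = logistic(fit.interface_lo, fit.rho_dense, fit.rho_dilute,
                          fit.r0, fit.w)
        assert lo_val == pytest.approx(0.9 * fit.rho_dense, rel=1e-6)


class TestPhaseConcentrations:
    def make_two_level_profile(self, rho_in=0.5, rho_out=0.01, r0=10.0, w=0.5):
        n = 120
        edges = np.arange(n + 1) * 0.25
        centers = 0.5 * (edges[:-1] + edges[1:])
        site_counts = np.full(n, 1000, dtype=np.int64)
        dens = np.where(centers < r0, rho_in, rho_out)
        from mixsep.condensate_geometry import RadialProfile, LogisticFit

        prof = RadialProfile(
            edges=edges, site_counts=site_counts,
            bead_counts={"A": dens * site_counts}, L=60, center=np.zeros(3),
        )
        fit = LogisticFit(rho_dense=rho_in, rho_dilute=rho_out, r0=r0, w=w)
        return prof, fit

    def test_recovers_constructed_levels_exactly(self):
        prof, fit = self.make_two_level_profile()
        c_dil, c_den = phase_concentrations(prof, fit, "A")
        assert c_den == pytest.approx(0.5)
        assert c_dil == pytest.approx(0.01)

    def test_interface_covering_box_flagged(self):
        prof, fit = self.make_two_level_profile(w=20.0)
        with pytest.raises(ValueError, match="two-phase"):
            phase_concentrations(prof, fit, "A")

    def test_species_concentrations_additive(self):
        prof, fit = self.make_two_level_profile()
        prof.bead_counts["B"] = 0.5 * prof.bead_counts["A"]
        da, Da = phase_concentrations(prof, fit, "A")
        db, Db = phase_concentrations(prof, fit, "B")
        assert Da + Db == pytest.approx(1.5 * Da)


class TestUnwrapAndRg:
    def test_unwrap_across_boundary(self):
        L = 10
        pts = np.array([[9, 0, 0], [0, 0, 0], [1, 0, 0]])
        u = unwrap_chain(pts, L)
        np.testing.assert_array_equal(u[:, 0], [9, 10, 11])

    def test_two_bead_chain_rg_half(self):
        assert chain_rg(np.array([[0, 0, 0], [0, 0, 1]]), 10) == pytest.approx(0.5)

    def test_rg_profile_two_bead_value(self):
        st = build_state([[(5, 5, 5), (5, 5, 6)]], L=16)
        prof = rg_profile(st, np.array([5.0, 5.0, 5.5]), min_beads=1)
        vals = prof.values["A"]
        defined = vals[~np.isnan(vals)]
        assert np.allclose(defined, 0.5 / math.sqrt(2))

    def test_bead_weighted_shell_means_match_manual(self):
        """Two chains with different Rg contribute bead-weighted means."""
        straight = [(8, 8, 8), (8, 8, 9), (8, 8, 10)]  # larger Rg
        compact = [(12, 12, 12), (12, 13, 12), (12, 12, 13)]
        st = build_state([straight, compact], L=24)
        center = np.array([8.0, 8.0, 8.0])
        prof = rg_profile(st, center, min_beads=1)
        rg1 = chain_rg(np.array(straight), 24) / math.sqrt(3)
        rg2 = chain_rg(np.array(compact), 24) / math.sqrt(3)
        d = st.positions - center
        r = np.sqrt((d**2).sum(axis=1))
        shells = (r / 0.25).astype(int)
        for s in np.unique(shells):
            beads = np.nonzero(shells == s)[0]
            expect = np.mean([rg1 if b < 3 else rg2 for b in beads])
            assert prof.values["A"][s] == pytest.approx(expect)


def test_rg_profile_reveals_interface_expansion_in_constructed_droplet():
    """Closed-loop check: a droplet built with compact chains in the core
    and extended chains at the surface shows its Rg/sqrt(N) peak at the
    construction's surface radius."""
    L = 32
    c = 16
    core, surface = [], []
    # compact 4-bead squares near the center
    for k, (dx, dy) in enumerate([(2, 0), (-3, 1), (0, 2), (1, -3)]):
        x, y, z = c + dx, c + dy, c + k - 2
        core.append([(x, y, z), (x + 1, y, z), (x, y + 1, z), (x + 1, y + 1, z)])
    # straight 4-bead rods tangent to a sphere of radius ~8
    for k, (dx, dy) in enumerate([(8, 0), (-8, 0), (0, 8), (0, -8)]):
        x, y, z = c + dx, c + dy, c + 4 * k - 8
        surface.append([(x, y, z + i) for i in range(4)])
    st = build_state(core + surface, L=L)
    prof = rg_profile(st, np.array([c, c, c], dtype=float), min_beads=2)
    vals = prof.values["A"]
    peak = prof.centers[np.nanargmax(vals)]
    assert 7.0 <= peak <= 9.5  # peak sits at the constructed surface shell
    # and the surface shells carry larger Rg/sqrt(N) than the core shells
    core_band = prof.centers < 5
    surf_band = (prof.centers >= 7) & (prof.centers <= 9.5)
    assert np.nanmean(vals[surf_band]) > np.nanmean(vals[core_band])


def test_mean_profile_is_site_weighted_average():
    p1, _ = make_logistic_profile(0.4, 0.0, 10.0, 1.0, n_shells=80)
    p2, _ = make_logistic_profile(0.2, 0.0, 10.0, 1.0, n_shells=80)
    m = mean_profile([p1, p2])
    d = m.density("synthetic")
    d1 = p1.density("synthetic")
    d2 = p2.density("synthetic")
    np.testing.assert_allclose(d, (d1 + d2) / 2, rtol=1e-12)
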