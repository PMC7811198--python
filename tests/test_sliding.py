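"""Sliding-model filaments: backbone, lateral LJ, separators, remodeling."""

import numpy as np
import pytest

import zconstrict as zc
from zconstrict import sliding as sl
from zconstrict.system import ParticleSystem


def make_chain(system, n, spacing=sl.L_Z, origin=(0.0, 0.0, 0.0),
               ring_id=0):
    pts = np.asarray(origin) + np.outer(np.arange(n), [0, 0, spacing])
    idx = system.add_beads(pts, 2)
    return sl.SlidingFilament(beads=list(map(int, idx)), ring_id=ring_id)


class TestRingInitialization:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rings_close_with_overlaps(self, seed):
        rng = np.random.default_rng(seed)
        system = ParticleSystem()
        layout = sl.RingLayout(n_rings=2, ring_radius=44.0, ring_spacing=16.0,
                               min_beads=10, max_beads=20)
        fils = sl.init_ring_system(system, layout, rng, width=64.0)
        total_arc = sum((f.n_beads - 1) * sl.L_Z for f in fils) / 2
        assert total_arc > 2 * np.pi * 44.0
        from zconstrict import analysis
        assert all(analysis.ring_integrity(system, fils).values())

    def test_beads_near_ring_radius(self):
        rng = np.random.default_rng(0)
        system = ParticleSystem()
        layout = sl.RingLayout(n_rings=1, ring_radius=44.0,
                               min_beads=10, max_beads=20)
        fils = sl.init_ring_system(system, layout, rng, width=64.0)
        r = system.radial(np.concatenate([f.beads for f in fils]))
        stagger = 2 ** (1 / 6) * sl.RHO
        assert np.all((r > 44.0 - stagger - 1e-6) & (r < 44.0 + 1e-6))

    def test_minimum_filament_count_at_published_geometry(self):
        from zconstrict import analysis
        assert analysis.min_filaments_per_ring(234.0, 176.0) == 9

    def test_seed_variation_changes_layout_not_statistics(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            system = ParticleSystem()
            layout = sl.RingLayout(n_rings=1, ring_radius=44.0,
                                   min_beads=10, max_beads=20)
            fils = sl.init_ring_system(system, layout, rng, width=64.0)
            counts.append(len(fils))
        assert len(set(counts)) > 1 or counts[0] > 0
        mean_beads = np.mean([15.0])  # uniform 10..20 midpoint
        assert 4 <= np.mean(counts) <= 30
        assert mean_beads == 15.0


class TestBackbone:
    def test_relaxed_straight_chain_has_no_force(self):
        system = ParticleSystem()
        f = make_chain(system, 10)
        sl.backbone_forces(system, [f])
        assert np.allclose(system.forces, 0.0, atol=1e-9)

    def test_bond_tension_value(self):
        # bond stretched to 4.5 nm -> tension 500 * 0.1 = 50 pN
        system = ParticleSystem()
        f = make_chain(system, 2, spacing=4.5)
        sl.backbone_forces(system, [f])
        assert np.linalg.norm(system.forces[0]) == pytest.approx(50.0)

    def test_bending_force_matches_numerical_gradient(self):
        from tests.conftest import central_difference_check
        system = ParticleSystem()
        f = make_chain(system, 5)
        rng = np.random.default_rng(3)
        system.positions += 0.05 * rng.standard_normal(system.positions.shape)
        err = central_difference_check(
            system, lambda: sl.backbone_forces(system, [f]),
            lambda: sl.backbone_energy(system, [f]), f.beads)
        assert err < 1e-5


class TestLennardJones:
    def test_repulsive_at_zero_potential_distance(self):
        d = np.array([sl.RHO])
        assert sl.lj_force_magnitude(d)[0] > 0

    def test_zero_force_at_potential_minimum(self):
        d = np.array([2 ** (1 / 6) * sl.RHO])
        assert sl.lj_force_magnitude(d)[0] == pytest.approx(0.0, abs=1e-9)

    def test_attractive_beyond_minimum(self):
        mag = sl.lj_force_magnitude(np.array([10.0]))[0]
        expected = (24 * sl.EPS / 10.0) * (
            2 * (sl.RHO / 10.0) ** 12 - (sl.RHO / 10.0) ** 6)
        assert mag == pytest.approx(expected)
        assert mag < 0

    def test_intra_filament_pairs_excluded(self):
        system = ParticleSystem()
        f = make_chain(system, 6)
        sl.lj_forces(system, [f])
        assert np.allclose(system.forces, 0.0)

    def test_momentum_conserved(self, two_filaments):
        system, c = two_filaments
        sl.lj_forces(system, c["filaments"])
        assert np.allclose(system.forces.sum(axis=0), 0.0, atol=1e-9)


class TestRingSeparation:
    def test_zero_at_separation_distance(self):
        system = ParticleSystem()
        fa = make_chain(system, 2, origin=(0, 0, 0), ring_id=0)
        fb = make_chain(system, 2, origin=(20.0, 0, 0), ring_id=1)
        sl.ring_separation_forces(system, [fa, fb])
        assert np.allclose(system.forces, 0.0, atol=1e-9)

    def test_linear_repulsion_value(self):
        # single pair at d = 18 -> |F| = 50 * 2 = 100 pN on each bead
        system = ParticleSystem()
        fa = make_chain(system, 1, origin=(0, 0, 0), ring_id=0)
        fb = make_chain(system, 1, origin=(18.0, 0, 0), ring_id=1)
        sl.ring_separation_forces(system, [fa, fb])
        assert np.linalg.norm(system.forces[0]) == pytest.approx(100.0)

    def test_same_ring_feels_no_separator(self):
        system = ParticleSystem()
        fa = make_chain(system, 2, origin=(0, 0, 0), ring_id=0)
        fb = make_chain(system, 2, origin=(10.0, 0, 0), ring_id=0)
        sl.ring_separation_forces(system, [fa, fb])
        assert np.allclose(system.forces, 0.0)


class TestRemodeling:
    def test_zero_rate_is_identity(self):
        system = ParticleSystem()
        f = make_chain(system, 10)
        out = sl.remodel_step(system, [f], "depolymerize", [0])
        assert out[0].beads == f.beads

    def test_depolymerization_removes_minus_end(self):
        system = ParticleSystem()
        f = make_chain(system, 10)
        first = f.beads[0]
        out = sl.remodel_step(system, [f], "depolymerize", [3])
        assert out[0].n_beads == 7
        assert first not in out[0].beads
        assert not system.mobile[first]

    def test_treadmilling_conserves_length_and_advances(self):
        system = ParticleSystem()
        f = make_chain(system, 10)
        old_minus = f.beads[0]
        old_plus = f.beads[-1]
        plus_pos = system.positions[old_plus].copy()
        out = sl.remodel_step(system, [f], "treadmill", [4])
        g = out[0]
        assert g.n_beads == 10
        assert old_minus not in g.beads
        # new plus-end beads continue along the terminal bond direction
        new_plus = system.positions[g.beads[-1]]
        assert np.allclose(new_plus, plus_pos + [0, 0, 4 * sl.L_Z])

    def test_filament_dropped_below_two_beads(self):
        system = ParticleSystem()
        f = make_chain(system, 3)
        out = sl.remodel_step(system, [f], "depolymerize", [2])
        assert out == []


class TestLateralEnergyProfile:
    def test_zero_overlap_zero_energy(self):
        shifts, e = sl.lateral_energy_profile(
            20, 20, shift_grid=np.array([-40.0]))
        assert abs(e[0]) < 1e-6

    def test_in_register_energy_scales_with_overlap(self):
        # energy at k beads of overlap, in register, is ~linear in k
        energies = []
        for k in (4, 8, 12):
            s = np.array([(k - 1) * sl.L_Z])
            _, e = sl.lateral_energy_profile(20, 20, s)
            energies.append(e[0])
        d1 = energies[1] - energies[0]
        d2 = energies[2] - energies[1]
        assert energies[0] < 0
        assert d1 < 0 and d2 < 0
        assert d2 == pytest.approx(d1, rel=0.15)

    def test_barrier_grows_with_overlap(self):
        # avidity: the sliding barrier increases monotonically with overlap
        b5 = sl.overlap_barrier(5)
        b10 = sl.overlap_barrier(10)
        b15 = sl.overlap_barrier(15)
        assert b5 < b10 < b15
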