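"""Membrane sheet: construction, pair forces, fluidity, bending, boundary."""

import numpy as np
import pytest

import zconstrict as zc
from zconstrict import membrane as mm
from zconstrict.system import ParticleSystem


@pytest.fixture(scope="module")
def full_membrane():
    system = ParticleSystem()
    m = mm.build_membrane_cylinder(system, 250.0, 160.0, 8.0, seed=0)
    return system, m


class TestConstruction:
    def test_beads_on_cylinder(self, full_membrane):
        system, m = full_membrane
        r = system.radial(m.bead_indices)
        assert np.allclose(r, 250.0, atol=1e-6)

    def test_ring_bead_count(self, full_membrane):
        system, m = full_membrane
        # beads per ring = round(2 pi 250 / 8) = 196
        x = system.positions[m.bead_indices, 0]
        counts = [np.sum(np.isclose(x, row)) for row in np.unique(np.round(x, 6))]
        assert set(counts) == {round(2 * np.pi * 250 / 8)}

    def test_axial_rows(self, full_membrane):
        system, m = full_membrane
        x = np.unique(np.round(system.positions[m.bead_indices, 0], 6))
        # periodic wrap: width/spacing distinct rows, no duplicated edge row
        assert len(x) == 160 // 8

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            mm.build_membrane_cylinder(ParticleSystem(), -5.0, 160.0, 8.0)
        with pytest.raises(ValueError):
            mm.build_membrane_cylinder(ParticleSystem(), 250.0, 161.0, 8.0)


class TestPairForces:
    def _two_bead_system(self, d):
        system = ParticleSystem()
        idx = system.add_beads([[0, 0, 0], [0, 0, d]], 0)
        m = mm.Membrane(bead_indices=idx, width=1e6, radius0=1.0)
        m.rep_i = np.array([idx[0]])
        m.rep_j = np.array([idx[1]])
        m.pair_i = np.array([idx[0]])
        m.pair_j = np.array([idx[1]])
        return system, m

    def test_zero_at_bead_size_boundary(self):
        system, m = self._two_bead_system(8.0)
        mm.membrane_pair_forces(system, m)
        assert np.allclose(system.forces, 0.0)

    def test_quadratic_repulsion(self):
        # d = 6, k_pair = 1 -> |F| = (8-6)^2 = 4 pN on each bead
        system, m = self._two_bead_system(6.0)
        mm.membrane_pair_forces(system, m)
        assert np.linalg.norm(system.forces[0]) == pytest.approx(4.0)
        assert np.allclose(system.forces[0], -system.forces[1])
        assert system.forces[0][2] < 0  # pushed apart

    def test_quadratic_attraction(self):
        # paired beads at d = 18 -> |F| = (18-16)^2 = 4 pN attractive
        system, m = self._two_bead_system(18.0)
        mm.membrane_pair_forces(system, m)
        assert np.linalg.norm(system.forces[0]) == pytest.approx(4.0)
        assert system.forces[0][2] > 0  # pulled together

    def test_total_force_is_zero(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        rng = np.random.default_rng(7)
        system.positions += 0.5 * rng.standard_normal(system.positions.shape)
        system.zero_forces()
        mm.membrane_pair_forces(system, m)
        assert np.allclose(system.forces.sum(axis=0), 0.0, atol=1e-9)


class TestFluidity:
    def test_rebuild_is_idempotent_on_static_lattice(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        before = m.pair_set
        mm.rebuild_pair_list(system, m)
        assert m.pair_set == before

    def test_one_crossing_allowed_two_removed(self):
        # hand-built flat patch: a long pair crossed by one shorter pair is
        # kept; crossed by two shorter pairs it is removed
        system = ParticleSystem()
        y = 100.0  # effectively flat tangent plane at large radius
        pts = [[0, y, 0], [10, y, 0],           # long pair along x
               [5, y, -4], [5, y, 4],           # short crossing pair
               [3, y, -4], [7, y, 4]]           # second crossing pair
        idx = system.add_beads(pts, 0)
        m = mm.Membrane(bead_indices=idx, width=1e4, radius0=y,
                        d_pair=16.0)
        mm.rebuild_pair_list(system, m)
        pairs = m.pair_set
        long_pair = (int(idx[0]), int(idx[1]))
        # candidate distance 10 < 16 so it is proposed; it is crossed by
        # the two shorter diagonals (8 nm) and the (4,5) pair -> removed
        assert long_pair not in pairs

    def test_quads_share_five_pairs(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        pairs = m.pair_set
        for quad in m.quads[:200]:
            a, c, b, d = (int(v) for v in quad)
            combos = [(a, c), (a, b), (a, d), (c, b), (c, d), (b, d)]
            n = sum((min(p), max(p)) in pairs for p in combos)
            assert n == 5
            # the absent pair is the second diagonal (b, d)
            assert (min(b, d), max(b, d)) not in pairs


class TestBending:
    def test_planar_quad_zero_force(self):
        system = ParticleSystem()
        idx = system.add_beads([[0, 50, 0], [0, 50, 8], [4, 50, 4],
                                [-4, 50, 4]], 0)
        m = mm.Membrane(bead_indices=idx, width=1e4, radius0=50.0)
        m.quads = np.array([[idx[0], idx[1], idx[2], idx[3]]])
        mm.membrane_bending_forces(system, m)
        assert np.allclose(system.forces, 0.0, atol=1e-12)

    def test_nonplanar_quad_restores(self):
        system = ParticleSystem()
        idx = system.add_beads([[0, 50, 0], [0, 50, 8], [4, 51, 4],
                                [-4, 51, 4]], 0)
        m = mm.Membrane(bead_indices=idx, width=1e4, radius0=50.0, k_mb=8.0)
        m.quads = np.array([[idx[0], idx[1], idx[2], idx[3]]])
        e0 = mm.membrane_bending_energy(system, m)
        mm.membrane_bending_forces(system, m)
        assert e0 > 0
        # net force and net torque vanish per quad
        assert np.allclose(system.forces.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(system.positions[idx],
                          system.forces[idx]).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-9)
        # descending the force direction lowers the energy
        system.positions[idx] += 1e-4 * system.forces[idx]
        assert mm.membrane_bending_energy(system, m) < e0


class TestCalibration:
    def test_reference_bending_energy_value(self):
        from zconstrict.units import joules
        # k_m_exp pi L / R with the published constants = 402 pN nm
        e = joules(2e-19) * np.pi * 160.0 / 250.0
        assert e == pytest.approx(402.12, abs=0.01)

    def test_calibration_linearity(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        k1 = mm.calibrate_kmb(system, m, 2e-19)
        k2 = mm.calibrate_kmb(system, m, 4e-19)
        assert k2 == pytest.approx(2 * k1)

    def test_calibrated_magnitude_order(self, full_membrane):
        system, m = full_membrane
        k = mm.calibrate_kmb(system, m)
        # same order of magnitude as the published 8 pN/nm; the exact value
        # depends on the mesh convention (quad count per bead)
        assert 0.8 <= k <= 80.0


class TestPeriodicBoundary:
    def test_edge_bead_images(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        idx, img = mm.periodic_images(system, m)
        x = system.positions[idx, 0]
        assert np.all((x < m.d_pair) | (x > m.width - m.d_pair))
        assert np.allclose(np.abs(img[:, 0] - x), m.width)

    def test_interior_beads_have_no_image(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        idx, _ = mm.periodic_images(system, m)
        interior = np.setdiff1d(m.bead_indices, idx)
        x = system.positions[interior, 0]
        assert np.all((x >= m.d_pair) & (x <= m.width - m.d_pair))

    def test_wrapped_distance_matches_translated_partner(self, mini_membrane):
        system, c = mini_membrane
        m = c["membrane"]
        # a bead at x~0 and one at x~width interact at their wrapped
        # separation, equal to the distance to the explicitly translated image
        i = m.bead_indices[np.argmin(system.positions[m.bead_indices, 0])]
        j = m.bead_indices[np.argmax(system.positions[m.bead_indices, 0])]
        vec = mm._pair_vectors(system, m, np.array([i]), np.array([j]))[0]
        translated = system.positions[j] - np.array([m.width, 0, 0])
        assert np.allclose(vec, translated - system.positions[i])
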