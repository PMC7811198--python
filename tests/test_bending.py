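"""Bending-model cube filaments: geometry, states, elasticity, treadmilling."""

import numpy as np
import pytest

import zconstrict as zc
from zconstrict import bending as bd
from zconstrict.system import ParticleSystem


class TestAngleDiameterRelation:
    @pytest.mark.parametrize("diameter,expected_deg", [
        (250.0, 2), (50.0, 10),
    ])
    def test_published_angle_values(self, diameter, expected_deg):
        assert round(bd.theta_from_diameter(diameter)) == expected_deg

    def test_round_trip(self):
        for d in (50.0, 64.0, 250.0, 500.0):
            assert bd.diameter_from_theta(
                bd.theta_from_diameter(d)) == pytest.approx(d, rel=1e-9)

    def test_rejects_tiny_diameter(self):
        with pytest.raises(ValueError):
            bd.theta_from_diameter(1.0)


class TestRelaxedLengthOffset:
    def test_offset_at_ten_degrees(self):
        # delta = 4.4 sin(5 deg) = 0.3835 nm
        assert bd.delta_l0(10.0) == pytest.approx(0.3835, abs=2e-4)

    def test_offset_at_two_degrees(self):
        assert bd.delta_l0(2.0) == pytest.approx(4.4 * np.sin(np.deg2rad(1.0)),
                                                 rel=1e-12)


class TestBendingSpringConstant:
    def test_value_at_ten_degrees(self):
        # k_theta theta^2 / (4 dl^2) ~ 196.8 pN/nm
        kb = bd.kb_from_eq2(np.deg2rad(10.0))
        assert kb == pytest.approx(196.8, abs=0.5)

    def test_linear_in_stiffness(self):
        a = bd.kb_from_eq2(0.1, k_theta=3800.0)
        b = bd.kb_from_eq2(0.1, k_theta=7600.0)
        assert b == pytest.approx(2 * a)

    def test_small_angle_limit(self):
        # dl ~ l_z theta / 2  ->  k_b -> k_theta / l_z^2, angle-independent
        kb = bd.kb_from_eq2(1e-4)
        assert kb == pytest.approx(3800.0 / 4.4 ** 2, rel=1e-6)


class TestConstruction:
    def test_shared_face_bead_counts(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 2)
        assert len(f.all_beads) == 12            # 8 + 4 shared-face beads
        system2 = ParticleSystem()
        f40 = bd.build_straight_cube_filament(system2, 40)
        assert len(f40.all_beads) == 4 + 40 * 4  # 164 unique beads

    def test_straight_build_is_relaxed(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 6)
        bd.cube_elastic_forces(system, f)
        assert np.allclose(system.forces, 0.0, atol=1e-8)

    def test_rejects_single_monomer(self):
        with pytest.raises(ValueError):
            bd.build_straight_cube_filament(ParticleSystem(), 1)


class TestBendingStates:
    def test_straight_state_equal_relaxed_lengths(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 4)
        bd.set_bending_state(f, bd.STRAIGHT, 10.0)
        assert f.dl0 == 0.0

    def test_bent_and_reverse_are_mirror_offsets(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 4)
        bd.set_bending_state(f, bd.BENT, 10.0)
        dl_bent = f.dl0
        bd.set_bending_state(f, bd.REVERSE_BENT, 10.0)
        assert f.dl0 == pytest.approx(-dl_bent)
        assert dl_bent == pytest.approx(bd.delta_l0(10.0))

    def test_unknown_state_rejected(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 4)
        with pytest.raises(ValueError):
            bd.set_bending_state(f, "wobbly")

    def test_bent_state_bends_toward_n_side_reverse_toward_c(self):
        # relaxing a free filament: traditional bending curves the chain so
        # the N faces are on the inside of the arc; reverse bending flips it
        from zconstrict.dynamics import IntegratorState, integrate_step
        curls = {}
        for state in (bd.BENT, bd.REVERSE_BENT):
            system = ParticleSystem()
            f = bd.build_straight_cube_filament(
                system, 8, axis=(0, 0, 1), c_dir=(0, 1, 0))
            bd.set_bending_state(f, state, 15.0)
            integ = IntegratorState(d_max=0.05)
            for _ in range(4000):
                system.zero_forces()
                bd.cube_elastic_forces(system, f)
                integrate_step(system, integ)
            c = f.centers(system)
            # mean curvature vector component along the C direction (+y)
            curv = (c[:-2] + c[2:] - 2 * c[1:-1]).mean(axis=0)
            curls[state] = curv[1]
        assert curls[bd.BENT] < 0 < curls[bd.REVERSE_BENT]

    def test_free_relaxation_reaches_preferred_curvature(self):
        # relaxed arc curvature within 5% of 2 sin(theta/2) / l_z
        from zconstrict.dynamics import IntegratorState, integrate_step
        theta = 15.0
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 10)
        bd.set_bending_state(f, bd.BENT, theta)
        integ = IntegratorState(d_max=0.05)
        for _ in range(12000):
            system.zero_forces()
            bd.cube_elastic_forces(system, f)
            integrate_step(system, integ)
        c = f.cube_centers(system)
        # circumscribed-circle curvature from chord geometry
        e = np.diff(c, axis=0)
        turn = []
        for a, b in zip(e[:-1], e[1:]):
            cosv = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            turn.append(np.arccos(np.clip(cosv, -1, 1)))
        seg = np.linalg.norm(e, axis=1).mean()
        kappa = np.mean(turn) / seg
        expected = 2 * np.sin(np.deg2rad(theta) / 2) / bd.L_Z
        assert kappa == pytest.approx(expected, rel=0.05)


class TestDivisionPlane:
    def test_in_plane_edge_feels_nothing(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 3, axis=(0, 0, 1),
                                            c_dir=(0, 1, 0))
        bd.division_plane_forces(system, f)
        # constrained edges are along y: no x-projection, no force
        assert np.allclose(system.forces, 0.0)

    def test_axial_projection_restoring_value(self):
        # edge with 1-nm axial projection -> 20 pN on each end bead
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 2, axis=(0, 0, 1),
                                            c_dir=(0, 1, 0))
        cs0 = f.cross_sections[0]
        system.positions[cs0[0], 0] += 1.0   # tip bead 1 out of the plane
        bd.division_plane_forces(system, f)
        assert abs(system.forces[cs0[0], 0]) == pytest.approx(20.0)
        assert abs(system.forces[cs0[3], 0]) == pytest.approx(20.0)
        # restoring: pushes the displaced bead back
        assert system.forces[cs0[0], 0] < 0


class TestTreadmilling:
    def test_zero_events_is_identity(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 5)
        before = [list(cs) for cs in f.cross_sections]
        bd.treadmill_cube_step(system, f, 0)
        assert [list(cs) for cs in f.cross_sections] == before

    def test_cube_count_conserved(self):
        system = ParticleSystem()
        f = bd.build_cube_filament(system, 8, ring_radius=44.0, center_x=0.0)
        for _ in range(14):
            f = bd.treadmill_cube_step(system, f, 1)
        assert f.n_monomers == 8

    def test_arc_following_keeps_radius(self):
        system = ParticleSystem()
        f = bd.build_cube_filament(system, 8, ring_radius=44.0, center_x=0.0)
        for _ in range(20):
            f = bd.treadmill_cube_step(system, f, 1)
        r = np.hypot(*f.cube_centers(system)[:, 1:].T)
        assert np.allclose(r, 44.0, atol=0.2)

    def test_two_monomer_filament_survives_treadmilling(self):
        # treadmilling conserves the cube count, so the 2-monomer minimum
        # is maintained, not crossed
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 2)
        out = bd.treadmill_cube_step(system, f, 1)
        assert out is not None and out.n_monomers == 2


class TestCubeExclusion:
    def test_no_force_beyond_onset(self):
        system = ParticleSystem()
        fa = bd.build_straight_cube_filament(system, 3, origin=(0, 0, 0))
        fb = bd.build_straight_cube_filament(system, 3, origin=(0, 10.0, 0))
        bd.cube_exclusion_forces(system, [fa, fb])
        assert np.allclose(system.forces, 0.0)

    def test_per_bead_magnitude(self):
        # centres 6.0 nm apart -> k_zz * 0.5 = 500 pN per bead pair axis
        system = ParticleSystem()
        fa = bd.build_straight_cube_filament(system, 2, origin=(0, 0, 0))
        fb = bd.build_straight_cube_filament(system, 2, origin=(0, 6.0, 0))
        bd.cube_exclusion_forces(system, [fa, fb])
        # beads of the end cross-section belong to one cube only and feel
        # exactly k_zz (d_zz - d); shared-face beads feel both cubes' pairs
        end = system.forces[fa.cross_sections[0], 1]
        shared = system.forces[fa.cross_sections[1], 1]
        assert np.allclose(np.abs(end), 500.0, rtol=0.01)
        assert np.allclose(np.abs(shared), 1000.0, rtol=0.01)

    def test_same_filament_excluded(self):
        system = ParticleSystem()
        f = bd.build_straight_cube_filament(system, 6)
        bd.cube_exclusion_forces(system, [f])
        assert np.allclose(system.forces, 0.0)
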