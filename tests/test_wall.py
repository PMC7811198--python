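"""Cell wall: geometry, glycan pre-stretch, turgor, coupling, growth."""

import numpy as np
import pytest

import zconstrict as zc
from zconstrict import wall as wl
from zconstrict import membrane as mm
from zconstrict.system import ParticleSystem
from zconstrict.units import atmospheres


@pytest.fixture(scope="module")
def full_wall():
    system = ParticleSystem()
    w = wl.build_wall(system, radius=265.0, width=160.0, spacing=16.0)
    return system, w


class TestGeometry:
    def test_published_bead_counts(self, full_wall):
        system, w = full_wall
        assert w.beads_per_hoop == 104            # round(2 pi 265 / 16)
        assert w.n_hoops == 11
        assert len(w.bead_indices) == 11 * 104

    def test_initial_gap_to_membrane(self):
        system = ParticleSystem()
        m = mm.build_membrane_cylinder(system, 250.0, 160.0, 8.0)
        w = wl.build_wall(system, radius=265.0, width=160.0,
                          membrane_radius=250.0)
        g, _ = wl.membrane_wall_gaps(system, w, m)
        assert np.allclose(g, 15.0, atol=0.35)

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            wl.build_wall(ParticleSystem(), radius=265.0,
                          membrane_radius=240.0)


class TestGlycanPreStretch:
    def test_published_relaxed_length(self):
        # l_g = 16 - (P r_g / k_g) l_p = 11.70 nm at 1 atm
        assert wl.initial_glycan_length() == pytest.approx(11.70, abs=0.01)

    def test_no_pressure_means_no_prestretch(self):
        assert wl.initial_glycan_length(p_tg=0.0) == pytest.approx(16.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            wl.initial_glycan_length(p_tg=atmospheres(5.0))

    def test_stretched_spring_tension(self):
        # glycan spring at 16 nm with l_g = 11.70 -> ~430 pN
        lg = wl.initial_glycan_length()
        assert 100.0 * (16.0 - lg) == pytest.approx(430.0, abs=1.0)


class TestTurgor:
    def test_enclosed_volume_matches_cylinder(self, full_wall):
        system, w = full_wall
        v = wl.enclosed_volume(system, w)
        assert v == pytest.approx(np.pi * 265.0 ** 2 * 160.0, rel=2e-3)

    def test_radial_force_per_bead(self, full_wall):
        # P_tg x (16 x 16 nm^2) ~ 25.9 pN outward per interior bead
        system, w = full_wall
        system.zero_forces()
        wl.turgor_forces(system, w)
        idx = w.grid[5]
        p = system.positions[idx].copy()
        p[:, 0] = 0
        rhat = p / np.linalg.norm(p, axis=1, keepdims=True)
        fr = np.einsum("ij,ij->i", system.forces[idx], rhat)
        assert fr.mean() == pytest.approx(25.9, rel=0.02)

    def test_net_axial_force_vanishes(self, full_wall):
        system, w = full_wall
        system.zero_forces()
        wl.turgor_forces(system, w)
        assert abs(system.forces[w.bead_indices, 0].sum()) < 1e-6


class TestEquilibrium:
    def test_wall_balances_at_build_radius(self, full_wall):
        system, w = full_wall
        system.zero_forces()
        wl.wall_elastic_forces(system, w)
        wl.turgor_forces(system, w)
        wl.apply_edge_tie(system, w)
        # net per-bead force is a tiny fraction of the ~26-pN turgor load
        assert np.abs(system.forces[w.bead_indices]).max() < 0.5


class TestEdgeTie:
    def test_edge_hoops_receive_identical_forces(self, full_wall):
        system, w = full_wall
        system.zero_forces()
        wl.wall_elastic_forces(system, w)
        wl.turgor_forces(system, w)
        wl.apply_edge_tie(system, w)
        assert np.allclose(system.forces[w.grid[0]],
                           system.forces[w.grid[-1]])

    def test_edge_hoops_are_translated_images(self, full_wall):
        system, w = full_wall
        d = system.positions[w.grid[-1]] - system.positions[w.grid[0]]
        assert np.allclose(d[:, 1:], 0.0, atol=1e-9)
        assert np.allclose(d[:, 0], 160.0)


class TestMembraneCoupling:
    @pytest.fixture()
    def coupled(self):
        system = ParticleSystem()
        m = mm.build_membrane_cylinder(system, 60.0, 64.0, 8.0)
        w = wl.build_wall(system, radius=75.0, width=64.0, spacing=16.0)
        return system, m, w

    def test_equilibrium_gap_means_no_force(self, coupled):
        system, m, w = coupled
        # move all membrane beads exactly 15 nm inside the wall
        g, _ = wl.membrane_wall_gaps(system, w, m)
        assert np.allclose(g, 15.0, atol=0.5)
        system.zero_forces()
        wl.wall_membrane_forces(system, w, m)
        assert np.abs(system.forces[m.bead_indices]).max() < 0.6

    def test_squeeze_is_quadratic_and_restoring(self, coupled):
        system, m, w = coupled
        # shrink the membrane by 2 nm: gap 17 -> 6.4 pN pulling back out
        pos = system.positions[m.bead_indices]
        r = np.hypot(pos[:, 1], pos[:, 2])
        scale = (r - 2.0) / r
        system.positions[m.bead_indices, 1] *= scale
        system.positions[m.bead_indices, 2] *= scale
        system.zero_forces()
        wl.wall_membrane_forces(system, w, m)
        f = system.forces[m.bead_indices]
        p = system.positions[m.bead_indices].copy()
        p[:, 0] = 0
        rhat = p / np.linalg.norm(p, axis=1, keepdims=True)
        fr = np.einsum("ij,ij->i", f, rhat)
        # outward (toward the wall), magnitude ~ k_w * 2^2 = 6.4 pN
        assert fr.mean() == pytest.approx(6.4, rel=0.15)


class TestGrowth:
    def _coupled_mini(self):
        system = ParticleSystem()
        m = mm.build_membrane_cylinder(system, 60.0, 64.0, 8.0)
        w = wl.build_wall(system, radius=75.0, width=64.0, spacing=16.0)
        return system, m, w

    def test_no_trigger_no_change(self):
        system, m, w = self._coupled_mini()
        lg0 = w.l_g.copy()
        policy = wl.WallGrowthPolicy()
        moved = wl.wall_growth_step(system, w, m, policy, dt_elapsed=1.0)
        assert moved == 0
        assert np.array_equal(w.l_g, lg0)

    def test_triggered_growth_shortens_two_springs(self):
        system, m, w = self._coupled_mini()
        # pull one membrane bead 1 nm inward -> its wall gap exceeds 15.5
        b = m.bead_indices[0]
        p = system.positions[b]
        r = np.hypot(p[1], p[2])
        system.positions[b, 1] *= (r - 1.0) / r
        system.positions[b, 2] *= (r - 1.0) / r
        lg0 = w.l_g.copy()
        policy = wl.WallGrowthPolicy(max_step_displacement=0.05)
        moved = wl.wall_growth_step(system, w, m, policy, dt_elapsed=10.0)
        assert moved >= 1
        changed = np.argwhere(w.l_g < lg0)
        assert len(changed) == 2 * moved
        # shortened by pi * 0.05 / N_b each
        shrink = (lg0 - w.l_g)[w.l_g < lg0]
        assert np.allclose(shrink, np.pi * 0.05 / w.beads_per_hoop)

    def test_rate_limited_displacement(self):
        system, m, w = self._coupled_mini()
        b = m.bead_indices[0]
        p = system.positions[b]
        r = np.hypot(p[1], p[2])
        system.positions[b, 1] *= (r - 1.0) / r
        system.positions[b, 2] *= (r - 1.0) / r
        lg0 = w.l_g.copy()
        # nu_w dt = 0.01 < 0.05 cap -> displacement limited to 0.01
        policy = wl.WallGrowthPolicy(nu_w=100.0, max_step_displacement=0.05)
        wl.wall_growth_step(system, w, m, policy, dt_elapsed=1e-4)
        shrink = (lg0 - w.l_g)[w.l_g < lg0]
        assert np.allclose(shrink, np.pi * 0.01 / w.beads_per_hoop)

    def test_growth_never_lengthens(self):
        system, m, w = self._coupled_mini()
        rng = np.random.default_rng(0)
        lg0 = w.l_g.copy()
        for _ in range(5):
            k = rng.integers(len(m.bead_indices))
            b = m.bead_indices[k]
            p = system.positions[b]
            r = np.hypot(p[1], p[2])
            system.positions[b, 1] *= (r - 1.0) / r
            system.positions[b, 2] *= (r - 1.0) / r
            wl.wall_growth_step(system, w, m, wl.WallGrowthPolicy(),
                                dt_elapsed=1.0)
        assert np.all(w.l_g <= lg0 + 1e-15)
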