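"""Overdamped Langevin dynamics with an adaptive, capped time step.

With inertia neglected (low Reynolds number, M = 0) the equation of
motion reduces to ``dX = F dt / γ``.  For stability the largest bead
displacement per step is capped at ``d_max``: every bead moves
``d_i = d_max · F_i / F_max`` along its force, and the corresponding
time step is ``dt = γ · d_max / F_max``, which therefore varies with
the instantaneous force spectrum.

Thermal motion is modeled as a random force ``k_rand · N(0,1)`` per
bead component, with the Gaussian deviates produced by the Box–Muller
transform of uniform pairs.  The random force is deliberately *not*
rescaled by √dt, so temperature is a force scale, not a physical
temperature.

The driver :class:`Simulation` owns the event schedule: neighbor-list
refreshes, membrane pair-list rebuilds (fluidity), cell-wall growth,
filament remodeling (depolymerization / treadmilling on a simulated-
time clock), metrics, and optional trajectory frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

import pandas as pd

from . import membrane as mem_mod
from . import sliding as sl
from . import bending as bd
from . import linkers as lk
from . import wall as wl
from .config import SimulationConfig, SLIDING, BENDING
from .system import ParticleSystem, FTSZ, MEMBRANE, WALL, LINKER, scatter_add

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thermal forces

def box_muller(rng: np.random.Generator, count: int) -> np.ndarray:
    """``count`` standard Gaussian deviates via the Box–Muller transform.

    ``r1 = cos(2π u2)·√(-2 ln u1)``, ``r2 = sin(2π u2)·√(-2 ln u1)``;
    u1 = 0 draws are resampled.
    """
    n_pairs = (count + 1) // 2
    u1 = rng.random(n_pairs)
    bad = u1 <= 0.0
    while bad.any():
        u1[bad] = rng.random(int(bad.sum()))
        bad = u1 <= 0.0
    u2 = rng.random(n_pairs)
    r = np.sqrt(-2.0 * np.log(u1))
    out = np.empty(2 * n_pairs)
    out[0::2] = r * np.cos(2 * np.pi * u2)
    out[1::2] = r * np.sin(2 * np.pi * u2)
    return out[:count]


def random_forces(system: ParticleSystem, k_rand: float,
                  rng: np.random.Generator, mask: np.ndarray) -> None:
    """Add ``k_rand × N(0,1)`` to every force component of masked beads."""
    if k_rand == 0.0:
        return
    n = int(mask.sum())
    if n == 0:
        return
    system.forces[mask] += k_rand * box_muller(rng, 3 * n).reshape(n, 3)


# ---------------------------------------------------------------------------
# FtsZ–membrane volume exclusion

def mz_exclusion_kernel(system: ParticleSystem, i, j, d_mz: float = 8.0,
                        k_mz: float = 200.0, accumulate: bool = True):
    """Harmonic repulsion between FtsZ and membrane beads below ``d_mz``."""
    if len(i) == 0:
        return 0.0
    vec = system.positions[j] - system.positions[i]
    d = np.maximum(np.linalg.norm(vec, axis=1), 1e-3)
    act = d < d_mz
    if not act.any():
        return 0.0
    i, j, vec, d = i[act], j[act], vec[act], d[act]
    if not accumulate:
        return float(0.5 * k_mz * np.sum((d_mz - d) ** 2))
    u = vec / d[:, None]
    f = -(k_mz * (d_mz - d))[:, None] * u
    scatter_add(system.forces, i, f)
    scatter_add(system.forces, j, -f)
    return 0.0


def mz_pair_candidates(system: ParticleSystem, ftsz_beads, mem_beads,
                       cutoff: float):
    if len(ftsz_beads) == 0 or len(mem_beads) == 0:
        return (np.empty(0, np.int64),) * 2
    tree = cKDTree(system.positions[mem_beads])
    hits = tree.query_ball_point(system.positions[ftsz_beads], cutoff)
    counts = np.fromiter((len(h) for h in hits), dtype=np.int64,
                         count=len(hits))
    if counts.sum() == 0:
        return (np.empty(0, np.int64),) * 2
    i = np.repeat(ftsz_beads, counts)
    j = mem_beads[np.concatenate([np.asarray(h, dtype=np.int64)
                                  for h in hits if h])]
    return i, j


# ---------------------------------------------------------------------------
# integrator

@dataclass
class IntegratorState:
    gamma: float = 1e-4       # pN·s/nm
    d_max: float = 0.01       # nm
    dt_max: float = 1e-6      # s
    t_sim: float = 0.0
    step: int = 0
    last_dt: float = 0.0


def integrate_step(system: ParticleSystem, state: IntegratorState) -> float:
    """Advance one step; returns the adaptive dt.

    ``d_i = d_max F_i / F_max`` along the force; ``dt = γ d_max / F_max``
    (capped at ``dt_max``; at zero force nothing moves and dt_max is
    consumed).  Immobile beads are excluded.
    """
    mob = system.mobile
    f = system.forces[mob]
    fmag = np.linalg.norm(f, axis=1)
    fmax = fmag.max() if len(fmag) else 0.0
    if fmax <= 1e-300:
        dt = state.dt_max
    else:
        dt = min(state.gamma * state.d_max / fmax, state.dt_max)
        system.positions[mob] += (dt / state.gamma) * f
    state.t_sim += dt
    state.step += 1
    state.last_dt = dt
    return dt


# ---------------------------------------------------------------------------
# simulation driver

@dataclass
class NeighborLists:
    lj_i: np.ndarray = None
    lj_j: np.ndarray = None
    lj_scale: np.ndarray | None = None
    sep_i: np.ndarray = None
    sep_j: np.ndarray = None
    cube_a8: np.ndarray = None
    cube_b8: np.ndarray = None
    mz_i: np.ndarray = None
    mz_j: np.ndarray = None
    wall_near: np.ndarray = None


class Simulation:
    """Assemble a scenario and integrate it.

    All randomness flows from one master seed through named child
    streams (build, thermal, remodel), so runs are bit-reproducible and
    components can be re-seeded in isolation.
    """

    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        kids = ss.spawn(3)
        self.rng_build = np.random.default_rng(kids[0])
        self.rng_thermal = np.random.default_rng(kids[1])
        self.rng_remodel = np.random.default_rng(kids[2])

        self.system = ParticleSystem()
        self.membrane = mem_mod.build_membrane_cylinder(
            self.system, cfg.mem_radius, cfg.mem_width, cfg.mem_spacing,
            seed=cfg.seed, d_mb=cfg.d_mb, d_pair=cfg.d_pair,
            k_pair=cfg.k_pair, k_mb=cfg.k_mb,
            rebuild_interval=cfg.pair_rebuild_interval)
        self.wall = None
        self.growth_policy = None
        if cfg.wall_enabled:
            self.wall = wl.build_wall(
                self.system, radius=cfg.wall_radius, width=cfg.mem_width,
                spacing=cfg.wall_spacing, membrane_radius=cfg.mem_radius,
                k_g=cfg.k_g, k_p=cfg.k_p, l_p=cfg.wall_spacing,
                p_tg=cfg.p_tg, k_w=cfg.k_w, d_wm=cfg.d_wm)
            self._lg0 = None  # set after wall build
            self.growth_policy = wl.WallGrowthPolicy(
                nu_w=cfg.nu_w, gap_trigger=cfg.gap_trigger,
                max_step_displacement=cfg.max_wall_step,
                update_interval=cfg.schedule_interval)

        if self.wall is not None:
            self._lg0 = self.wall.l_g.copy()
        self.filaments: list = []
        self.linker_sets: list[lk.LinkerSet] = []
        self._build_filaments()
        for f in self.filaments:
            self.linker_sets.append(lk.attach_linkers(
                self.system, f, self.membrane, variant=cfg.linker_variant,
                spacing=cfg.linker_spacing, capture_radius=cfg.capture_radius,
                k_lk=cfg.k_lk, l_lk=cfg.l_lk, k_c=cfg.k_c, k_r=cfg.k_r))

        self.integrator = IntegratorState(
            gamma=cfg.gamma, d_max=cfg.d_max, dt_max=cfg.dt_max)
        self.nl = NeighborLists()
        self._cube_batch = None
        self._merged_linkers = None
        self._thermal_mask = self._make_thermal_mask()
        if cfg.remodel_rate > 0:
            self._next_event_time = (
                self.rng_remodel.exponential(1.0 / cfg.remodel_rate)
                if cfg.poisson_remodel else 1.0 / cfg.remodel_rate)
        else:
            self._next_event_time = np.inf
        self._last_growth_t = 0.0
        self.metrics_rows: list[dict] = []
        self.frame_writer = None
        self.refresh_neighbor_lists()

    # -- construction -------------------------------------------------

    def _build_filaments(self):
        cfg = self.cfg
        if cfg.model == SLIDING:
            layout = sl.RingLayout(
                n_rings=cfg.n_rings, ring_radius=cfg.ring_radius,
                ring_spacing=cfg.ring_spacing, min_beads=cfg.fil_min_beads,
                max_beads=cfg.fil_max_beads,
                overlap_factor=cfg.overlap_factor)
            self.filaments = sl.init_ring_system(
                self.system, layout, self.rng_build, width=cfg.mem_width)
        elif cfg.model == BENDING:
            n = cfg.n_bend_filaments
            circ_angle = 2 * np.pi / max(n, 1)
            for k in range(n):
                sense = 1 if self.rng_build.random() < 0.5 else -1
                f = bd.build_cube_filament(
                    self.system, cfg.bend_monomers, cfg.ring_radius,
                    center_x=cfg.mem_width / 2.0,
                    theta_start=k * circ_angle, sense=sense,
                    k_z=cfg.k_z, ring_id=0,
                    tilt_deg=cfg.bend_tilt_deg)
                # all filaments hydrolyse at t = 0
                bd.set_bending_state(f, cfg.bend_state, cfg.theta_b_deg,
                                     k_theta=cfg.k_theta)
                self.filaments.append(f)

    def _make_thermal_mask(self) -> np.ndarray:
        m = self.system.mobile.copy()
        if not self.cfg.thermal_wall:
            m &= self.system.tags != WALL
        if not self.cfg.thermal_joints:
            m &= self.system.tags != LINKER
        return m

    # -- neighbor lists ------------------------------------------------

    def refresh_neighbor_lists(self):
        cfg = self.cfg
        skin = cfg.neighbor_skin
        mem_mod.rebuild_repulsion_list(self.system, self.membrane, skin=skin)
        nl = self.nl
        if cfg.model == SLIDING and self.filaments:
            cutoff = sl.LJ_CUTOFF_FACTOR * cfg.rho + skin
            nl.lj_i, nl.lj_j = sl._interfilament_pairs(
                self.system, self.filaments, cutoff)
            nl.lj_scale = self._eps_scale(nl.lj_i, nl.lj_j)
            if cfg.separators:
                nl.sep_i, nl.sep_j = sl._interfilament_pairs(
                    self.system, self.filaments, cfg.d_s + skin,
                    same_ring_only=False)
            else:
                nl.sep_i = nl.sep_j = np.empty(0, np.int64)
        if cfg.model == BENDING and self.filaments:
            nl.cube_a8, nl.cube_b8 = bd.cube_pair_candidates(
                self.system, self.filaments, cfg.d_zz + skin)
            self._cube_batch = bd.cube_batch(self.filaments)
        ftsz = np.where((self.system.tags == FTSZ) & self.system.mobile)[0]
        nl.mz_i, nl.mz_j = mz_pair_candidates(
            self.system, ftsz, self.membrane.bead_indices, cfg.d_mz + skin)
        if self.wall is not None:
            nl.wall_near = wl.nearest_wall_map(
                self.system, self.wall, self.membrane)
        self._merged_linkers = lk.merge_linker_sets(self.linker_sets)
        self._thermal_mask = self._make_thermal_mask()

    def _eps_scale(self, i, j):
        """Per-pair ε multiplier from parallel/antiparallel classification."""
        cfg = self.cfg
        if cfg.s_par == 1.0 and cfg.s_anti == 1.0:
            return None
        pol = np.zeros(self.system.n_beads, dtype=np.int8)
        for f in self.filaments:
            pol[np.asarray(f.beads)] = f.polarity
        par = pol[i] == pol[j]
        return np.where(par, cfg.s_par, cfg.s_anti)

    # -- forces --------------------------------------------------------

    def accumulate_forces(self, thermal: bool = True):
        cfg = self.cfg
        sys_ = self.system
        sys_.zero_forces()
        mem_mod.membrane_pair_forces(sys_, self.membrane, self.rng_thermal)
        mem_mod.membrane_bending_forces(sys_, self.membrane)
        if self.wall is not None:
            wl.wall_elastic_forces(sys_, self.wall)
            wl.turgor_forces(sys_, self.wall)
            wl.wall_membrane_forces(sys_, self.wall, self.membrane,
                                    near=self.nl.wall_near)
        if cfg.model == SLIDING and self.filaments:
            sl.backbone_forces(sys_, self.filaments)
            sl.lj_kernel(sys_, self.nl.lj_i, self.nl.lj_j, cfg.eps, cfg.rho,
                         eps_scale=self.nl.lj_scale)
            if cfg.separators:
                sl.ring_sep_kernel(sys_, self.nl.sep_i, self.nl.sep_j,
                                   cfg.d_s, cfg.k_s)
        elif cfg.model == BENDING and self.filaments:
            bd.cube_batch_forces(sys_, self._cube_batch,
                                 division_plane=cfg.division_plane,
                                 k_dp=cfg.k_dp)
            bd.cube_exclusion_kernel(sys_, self.nl.cube_a8, self.nl.cube_b8,
                                     cfg.d_zz, cfg.k_zz)
        if self._merged_linkers is not None:
            lk.linker_forces(sys_, self._merged_linkers)
        mz_exclusion_kernel(sys_, self.nl.mz_i, self.nl.mz_j,
                            cfg.d_mz, cfg.k_mz)
        if thermal and cfg.k_rand > 0:
            random_forces(sys_, cfg.k_rand, self.rng_thermal,
                          self._thermal_mask)
        if self.wall is not None:
            wl.apply_edge_tie(sys_, self.wall)
        sys_.forces[~sys_.mobile] = 0.0

    def total_energy(self) -> float:
        """Potential energy of all deterministic force terms (same lists)."""
        cfg = self.cfg
        sys_ = self.system
        e = mem_mod.membrane_pair_energy(sys_, self.membrane)
        e += mem_mod.membrane_bending_energy(sys_, self.membrane)
        if self.wall is not None:
            e += wl.wall_elastic_energy(sys_, self.wall)
            e += wl.turgor_energy(sys_, self.wall)
            e += wl.wall_membrane_energy(sys_, self.wall, self.membrane,
                                         near=self.nl.wall_near)
        if cfg.model == SLIDING and self.filaments:
            e += sl.backbone_energy(sys_, self.filaments)
            e += sl.lj_kernel(sys_, self.nl.lj_i, self.nl.lj_j, cfg.eps,
                              cfg.rho, eps_scale=self.nl.lj_scale,
                              accumulate=False)
            if cfg.separators:
                e += sl.ring_sep_kernel(sys_, self.nl.sep_i, self.nl.sep_j,
                                        cfg.d_s, cfg.k_s, accumulate=False)
        elif cfg.model == BENDING and self.filaments:
            for f in self.filaments:
                e += bd.cube_elastic_energy(sys_, f)
                if cfg.division_plane:
                    e += bd.division_plane_energy(sys_, f, cfg.k_dp)
            e += bd.cube_exclusion_kernel(sys_, self.nl.cube_a8,
                                          self.nl.cube_b8, cfg.d_zz,
                                          cfg.k_zz, accumulate=False)
        if self._merged_linkers is not None:
            e += lk.linker_energy(sys_, self._merged_linkers)
        e += mz_exclusion_kernel(sys_, self.nl.mz_i, self.nl.mz_j,
                                 cfg.d_mz, cfg.k_mz, accumulate=False)
        return e

    # -- scheduled events ----------------------------------------------

    def _remodel_events(self):
        cfg = self.cfg
        if cfg.remodel_rate <= 0 or not self.filaments:
            return
        t = self.integrator.t_sim
        events = 0
        while self._next_event_time <= t:
            events += 1
            if cfg.poisson_remodel:
                self._next_event_time += self.rng_remodel.exponential(
                    1.0 / cfg.remodel_rate)
            else:
                self._next_event_time += 1.0 / cfg.remodel_rate
        if events == 0:
            return
        kept_f, kept_l = [], []
        for f, lset in zip(self.filaments, self.linker_sets):
            if cfg.model == SLIDING:
                mode = ("treadmill" if cfg.remodel_mode == "treadmill"
                        else "depolymerize")
                out = sl.remodel_step(self.system, [f], mode, [events])
                survived = bool(out)
            else:
                survived = bd.treadmill_cube_step(
                    self.system, f, events) is not None
            if survived:
                lk.sync_after_remodel(self.system, lset, f, self.membrane)
                kept_f.append(f)
                kept_l.append(lset)
            else:
                if lset.joints is not None:
                    for jb in lset.joints:
                        self.system.mobile[jb] = False
                        self.system.positions[jb] = 1e6
        self.filaments, self.linker_sets = kept_f, kept_l
        self.refresh_neighbor_lists()

    def _growth(self):
        if self.wall is None:
            return
        dt_el = self.integrator.t_sim - self._last_growth_t
        self._last_growth_t = self.integrator.t_sim
        wl.wall_growth_step(self.system, self.wall, self.membrane,
                            self.growth_policy, dt_el, near=self.nl.wall_near)

    def record_metrics(self):
        from . import analysis
        sys_ = self.system
        row = {
            "t": self.integrator.t_sim,
            "step": self.integrator.step,
            "mem_radius": float(sys_.radial(self.membrane.bead_indices).mean()),
            "n_filaments": len(self.filaments),
        }
        if self.wall is not None:
            row["wall_radius"] = self.wall.mean_radius(sys_)
            row["wall_volume"] = wl.enclosed_volume(sys_, self.wall)
            row["wall_grown"] = float((self._lg0 - self.wall.l_g).sum())
        if self.cfg.model == SLIDING and self.filaments:
            intact = analysis.ring_integrity(
                sys_, self.filaments,
                bridge_tolerance=sl.LJ_CUTOFF_FACTOR * self.cfg.rho)
            row["rings_intact"] = int(all(intact.values()))
            row["inter_ring_distance"] = analysis.inter_ring_distance(
                sys_, self.filaments)
        if self.filaments:
            summ = analysis.filament_membrane_distance(
                sys_, self.filaments, self.membrane)
            row["fil_mem_distance"] = summ["mean"]
        self.metrics_rows.append(row)

    # -- main loop ------------------------------------------------------

    def run(self, n_steps: int | None = None, thermal: bool = True,
            record: bool = True) -> "Simulation":
        cfg = self.cfg
        n_steps = cfg.step_budget if n_steps is None else n_steps
        if record and not self.metrics_rows:
            self.record_metrics()
        for k in range(n_steps):
            self.accumulate_forces(thermal=thermal)
            integrate_step(self.system, self.integrator)
            step = self.integrator.step
            if step % cfg.neighbor_interval == 0:
                self.refresh_neighbor_lists()
            if step % self.membrane.rebuild_interval == 0:
                mem_mod.rebuild_pair_list(self.system, self.membrane)
            if step % cfg.schedule_interval == 0:
                self._growth()
                self._remodel_events()
                if record:
                    self.record_metrics()
                if not np.isfinite(
                        self.system.positions[self.system.mobile]).all():
                    raise FloatingPointError(
                        f"non-finite coordinates at step {step}")
                if self.frame_writer is not None:
                    self.frame_writer(self)
        if record and (not self.metrics_rows
                       or self.metrics_rows[-1]["step"] != self.integrator.step):
            self.record_metrics()
        return self

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics_rows)


def run_simulation(cfg: SimulationConfig, out_dir=None) -> Simulation:
    """Build and run a scenario; optionally write trajectory + metrics.

    Fully reproducible: identical config (including seed) gives
    bit-identical trajectories.
    """
    sim = Simulation(cfg)
    if out_dir is not None:
        from . import io as io_mod
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if cfg.frame_interval > 0:
            traj = out / "trajectory.xyz"
            traj.write_text("")
            sim.frame_writer = lambda s: io_mod.write_frame(
                s.system, traj, mode="a")
        sim.run()
        sim.metrics.to_csv(out / "metrics.csv", index=False)
        io_mod.write_manifest(cfg, out / "manifest.json")
        io_mod.write_frame(sim.system, out / "final.xyz")
    else:
        sim.run()
    return sim
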