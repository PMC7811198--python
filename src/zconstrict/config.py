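"""Scenario configuration.

All internal values are in nm / pN / s (energies pN·nm).  Literature
constants quoted in J or atm are converted here, at the boundary —
nowhere else.  Scenario presets mirror the study conditions summarized
in the model-comparison table: each adds one mechanistic ingredient to
the core model (LJ attraction, ring separators, depolymerization,
treadmilling, bending, constrained linkers, rigid linkers, reverse
bending, a single filament).

``scale="full"`` is the as-published geometry (250-nm membrane, 1 atm,
0.01-nm step cap) whose production runs take billions of steps;
``scale="mini"`` is a small, accelerated system for testing and
qualitative exploration (smaller cylinder, larger step cap, remodeling
and wall-growth clocks sped up by a common factor so rate *ratios* are
preserved).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict

import yaml

from .units import joules, atmospheres

log = logging.getLogger(__name__)

SLIDING, BENDING = "sliding", "bending"


@dataclass
class SimulationConfig:
    scenario: str = "sliding_depoly"
    scale: str = "full"
    seed: int = 0
    step_budget: int = 100_000
    model: str = SLIDING

    # membrane
    mem_radius: float = 250.0
    mem_width: float = 160.0
    mem_spacing: float = 8.0
    k_pair: float = 1.0
    d_mb: float = 8.0
    d_pair: float = 16.0
    k_mb: float = 8.0
    pair_rebuild_interval: int = 10_000

    # cell wall (radius = mem_radius + d_wm)
    wall_enabled: bool = True
    wall_spacing: float = 16.0
    p_tg: float = atmospheres(1.0)
    k_g: float = 100.0
    k_p: float = 10.0
    k_w: float = 1.6
    d_wm: float = 15.0
    nu_w: float = 100.0
    gap_trigger: float = 0.5
    max_wall_step: float = 0.05
    schedule_interval: int = 10_000

    # sliding filaments (ring radius = mem_radius - 16)
    n_rings: int = 2
    ring_spacing: float = 20.0
    fil_min_beads: int = 20
    fil_max_beads: int = 60
    eps: float = joules(5e-19)
    rho: float = 6.5
    k_z: float = 500.0
    k_theta: float = joules(3.8e-18)
    separators: bool = True
    d_s: float = 20.0
    k_s: float = 50.0
    s_par: float = 1.0
    s_anti: float = 1.0
    overlap_factor: float = 1.3         # ring arc length / circumference
    remodel_mode: str = "none"          # none | depolymerize | treadmill
    remodel_rate: float = 0.0           # beads (monomers) per second
    poisson_remodel: bool = False

    # bending filaments
    bend_state: str = "bent"            # straight | bent | reverse_bent
    theta_b_deg: float = 10.0
    n_bend_filaments: int = 8
    bend_monomers: int = 40
    k_dp: float = 20.0
    division_plane: bool = False
    #: initial rotation of the bending plane out of the division plane
    #: (probes the rolling instability; 0 = perfectly in-plane)
    bend_tilt_deg: float = 0.0

    # linkers
    linker_variant: str = "flexible"    # flexible | circumferential | rigid
    linker_spacing: int = 4
    capture_radius: float = 24.0
    k_lk: float = 20.0
    l_lk: float = 8.0
    k_c: float = 20.0
    k_r: float = 3.0

    # volume exclusion
    k_mz: float = 200.0
    d_mz: float = 8.0
    k_zz: float = 1000.0
    d_zz: float = 6.5

    # integrator
    gamma: float = 1e-4                 # pN·s/nm (1e-7 N·s/m)
    d_max: float = 0.01                 # nm, per-step displacement cap
    k_rand: float = 5.0                 # pN, thermal force scale
    dt_max: float = 1e-6                # s, guards the F_max -> 0 limit
    thermal_wall: bool = True
    thermal_joints: bool = True
    neighbor_interval: int = 100
    neighbor_skin: float = 2.0
    random_refresh_interval: int = 1

    # output
    frame_interval: int = 0             # steps between frames (0 = no frames)

    @property
    def ring_radius(self) -> float:
        return self.mem_radius - 16.0

    @property
    def wall_radius(self) -> float:
        return self.mem_radius + self.d_wm

    def validate(self) -> None:
        errors = []
        for name in ("mem_radius", "mem_width", "mem_spacing", "k_pair",
                     "k_mb", "k_g", "k_p", "k_z", "k_theta", "gamma", "d_max"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.scenario not in SCENARIOS:
            errors.append(f"unknown scenario {self.scenario!r}")
        if self.scale not in ("full", "mini"):
            errors.append(f"unknown scale {self.scale!r}")
        if self.remodel_mode not in ("none", "depolymerize", "treadmill"):
            errors.append(f"unknown remodel_mode {self.remodel_mode!r}")
        if self.linker_variant not in ("flexible", "circumferential", "rigid"):
            errors.append(f"unknown linker_variant {self.linker_variant!r}")
        if self.remodel_rate < 0:
            errors.append("remodel_rate must be >= 0")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        if (self.remodel_mode == "treadmill" and self.scale == "full"
                and self.remodel_rate > 14.0):
            log.warning("treadmilling rate %.1f beads/s exceeds the 14/s "
                        "range explored", self.remodel_rate)

    def to_dict(self) -> dict:
        return asdict(self)


# unit-convenience YAML keys -> (field, converter)
_UNIT_KEYS = {
    "eps_J": ("eps", joules),
    "k_theta_J": ("k_theta", joules),
    "p_tg_atm": ("p_tg", atmospheres),
    "preferred_diameter_nm": ("theta_b_deg", None),   # handled specially
}

_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}

#: per-scenario overrides on top of the defaults
SCENARIOS: dict[str, dict] = {
    # filament sliding
    "sliding_lj": dict(model=SLIDING, separators=False, remodel_mode="none"),
    "sliding_separated": dict(model=SLIDING, separators=True,
                              remodel_mode="none"),
    "sliding_depoly": dict(model=SLIDING, separators=True,
                           remodel_mode="depolymerize", remodel_rate=1.0,
                           nu_w=100.0),
    "sliding_treadmill": dict(model=SLIDING, separators=True,
                              remodel_mode="treadmill", remodel_rate=1.0),
    # filament bending (500-nm start diameter; curved-filament diameter 50 nm)
    "bending_free": dict(model=BENDING, bend_state="bent", theta_b_deg=10.0,
                         linker_variant="flexible", division_plane=False),
    "bending_circumferential": dict(model=BENDING, bend_state="bent",
                                    theta_b_deg=10.0,
                                    linker_variant="circumferential",
                                    division_plane=False),
    "bending_rigid": dict(model=BENDING, bend_state="bent", theta_b_deg=10.0,
                          linker_variant="rigid", division_plane=True,
                          l_lk=16.0, remodel_mode="treadmill",
                          remodel_rate=14.0),
    # curved-filament diameter 250 nm on the 500-nm membrane
    "bending_reverse": dict(model=BENDING, bend_state="reverse_bent",
                            theta_b_deg=2.016, linker_variant="rigid",
                            division_plane=True, l_lk=16.0,
                            remodel_mode="treadmill", remodel_rate=14.0),
    # single filament, preferred curvature 1/32 nm^-1 (diameter 64 nm)
    "single_filament": dict(model=BENDING, bend_state="reverse_bent",
                            theta_b_deg=7.878, n_bend_filaments=1,
                            linker_variant="rigid", division_plane=True,
                            l_lk=16.0, remodel_mode="treadmill",
                            remodel_rate=14.0),
}

#: geometry/clock overrides for the accelerated test scale.  The common
#: rate factor speeds remodeling and wall growth together, preserving
#: rate ratios (the critical-rate logic) at desk-scale step budgets.
MINI_RATE_FACTOR = 2e3

_MINI = dict(
    scale="mini",
    mem_radius=60.0, mem_width=64.0,
    n_rings=2, ring_spacing=16.0,
    fil_min_beads=10, fil_max_beads=20,
    overlap_factor=2.0,
    n_bend_filaments=3, bend_monomers=14,
    d_max=0.1, neighbor_interval=20, neighbor_skin=4.0,
    pair_rebuild_interval=2_000, schedule_interval=125,
    max_wall_step=0.05,
    # growth trigger scaled with the 10x larger displacement cap so membrane
    # position noise alone does not ratchet the wall inward
    gap_trigger=2.0,
    step_budget=30_000,
)


def make_config(scenario: str = "sliding_depoly", scale: str = "full",
                seed: int = 0, **overrides) -> SimulationConfig:
    """Build a validated config from a scenario preset plus overrides."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from "
                         f"{sorted(SCENARIOS)}")
    values: dict = dict(scenario=scenario, seed=seed)
    values.update(SCENARIOS[scenario])
    if scale == "mini":
        values.update(_MINI)
        # accelerate the remodeling / growth clocks by the common factor
        values["remodel_rate"] = values.get(
            "remodel_rate", 0.0) * MINI_RATE_FACTOR
        values["nu_w"] = values.get("nu_w", 100.0) * MINI_RATE_FACTOR
        # keep mini bending filaments curvier than the mini membrane but
        # within the explored 1-20 degree band
        if values.get("model") == BENDING:
            values.setdefault("theta_b_deg", 10.0)
    values.update(_translate_unit_keys(overrides))
    unknown = set(values) - _FIELDS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = SimulationConfig(**values)
    cfg.validate()
    return cfg


def _translate_unit_keys(d: dict) -> dict:
    from .bending import theta_from_diameter
    out = {}
    for k, v in d.items():
        if k == "preferred_diameter_nm":
            out["theta_b_deg"] = theta_from_diameter(float(v))
        elif k in _UNIT_KEYS:
            name, conv = _UNIT_KEYS[k]
            out[name] = conv(float(v))
        else:
            out[k] = v
    return out


def load_config(path) -> SimulationConfig:
    """Load a YAML scenario file; unknown keys are rejected.

    An empty file yields the default configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    scenario = raw.pop("scenario", "sliding_depoly")
    scale = raw.pop("scale", "full")
    seed = int(raw.pop("seed", 0))
    return make_config(scenario, scale, seed, **raw)


def dump_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
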