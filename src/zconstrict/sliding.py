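"""Bead-chain FtsZ filaments for the filament-sliding hypothesis.

Each filament is a polar chain of beads (minus end at index 0, plus end
last), one bead per FtsZ monomer, with

* backbone springs of relaxed length ``l_z`` = 4.4 nm and a stiff
  constant ``k_z`` = 500 pN/nm,
* a harmonic bending penalty ``E_theta = k_theta (θ - θ0)²/2`` at every
  interior bead (θ0 = 0, i.e. straight preferred),
* a 12-6 Lennard-Jones lateral interaction between beads on *different*
  filaments (force magnitude ``(24 ε/d)[2(ρ/d)^12 - (ρ/d)^6]``, positive
  = repulsive), which provides the long-range attraction the sliding
  mechanism requires as well as filament–filament volume exclusion,
* an optional ring separator: beads on different rings repel below
  ``d_s`` = 20 nm with ``k_s (d_s - d)``, which prevents ring bundling,
* depolymerization (minus-end bead removal) and treadmilling (plus-end
  addition + minus-end removal at the same rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import cross3, row_norm, ParticleSystem, FTSZ, scatter_add

log = logging.getLogger(__name__)

L_Z = 4.4          # nm, monomer spacing
K_Z = 500.0        # pN/nm
K_THETA = 3800.0   # pN·nm (3.8e-18 J)
EPS = 500.0        # pN·nm (5e-19 J)
RHO = 6.5          # nm, LJ zero-potential distance
D_S = 20.0         # nm, ring-separator onset
K_S = 50.0         # pN/nm
LJ_CUTOFF_FACTOR = 3.0   # cutoff = 3 ρ; force there is <0.3 % of the well force
MIN_DIST = 1e-3


@dataclass
class SlidingFilament:
    """Polar bead chain; ``beads[0]`` is the minus end."""
    beads: list[int]
    ring_id: int = 0
    #: +1 / -1: treadmilling direction around the ring (fixed at init)
    polarity: int = 1
    l_z: float = L_Z
    k_z: float = K_Z
    k_theta: float = K_THETA
    theta0: float = 0.0

    @property
    def n_beads(self) -> int:
        return len(self.beads)


@dataclass
class RingLayout:
    """Placement recipe for overlapping-filament rings."""
    n_rings: int = 2
    ring_radius: float = 234.0
    ring_spacing: float = 20.0          # axial separation of adjacent rings, nm
    min_beads: int = 20
    max_beads: int = 60
    center_x: float | None = None       # default: centered on the membrane width
    overlap_factor: float = 1.3        # total arc length / circumference


def init_ring_system(system: ParticleSystem, layout: RingLayout,
                     rng: np.random.Generator,
                     width: float = 160.0) -> list[SlidingFilament]:
    """Place filaments on circles so each ring closes with overlaps.

    Filament bead counts are drawn uniformly from
    ``[min_beads, max_beads]``; filaments are appended around the circle
    until the summed arc length exceeds ``overlap_factor`` times the
    circumference, then spread so overlaps are distributed.  Polarity
    (treadmilling direction) is assigned randomly per filament.
    """
    circumference = 2 * np.pi * layout.ring_radius
    x0 = width / 2 if layout.center_x is None else layout.center_x
    x_start = x0 - (layout.n_rings - 1) * layout.ring_spacing / 2
    filaments: list[SlidingFilament] = []
    # head-to-tail placement with guaranteed end overlaps closes each ring;
    # overlapping neighbours are staggered radially by the pair distance so
    # overlaps sit near the lateral-potential minimum instead of on top of
    # each other (an even per-ring count keeps the stagger consistent
    # around the wrap).  Polarity only selects which geometric end is the
    # minus end.
    stagger = 2.0 ** (1.0 / 6.0) * RHO
    for ring in range(layout.n_rings):
        x = x_start + ring * layout.ring_spacing
        counts = []
        total = 0.0
        while total < layout.overlap_factor * circumference or len(counts) % 2:
            n = int(rng.integers(layout.min_beads, layout.max_beads + 1))
            counts.append(n)
            total += (n - 1) * L_Z
        if total < circumference:
            raise ValueError("total filament arc length below circumference; "
                             "ring cannot close")
        # distribute the arc excess over the junction overlaps: a floor of
        # two subunits per junction (so no junction is a single weak
        # contact), the rest randomly
        excess = total - circumference
        floor = min(2.0 * L_Z, 0.5 * excess / len(counts))
        w = rng.dirichlet(np.ones(len(counts)))
        overlaps = floor + (excess - floor * len(counts)) * w
        th = rng.uniform(0.0, 2 * np.pi)
        for k, n in enumerate(counts):
            sense = 1 if rng.random() < 0.5 else -1
            r_k = layout.ring_radius - (k % 2) * stagger
            dtheta = L_Z / r_k
            angles = th + dtheta * np.arange(n)
            pts = np.column_stack([
                np.full(n, x),
                r_k * np.cos(angles),
                r_k * np.sin(angles),
            ])
            idx = system.add_beads(pts, FTSZ)
            beads = list(map(int, idx))
            if sense < 0:
                beads.reverse()      # minus end at the other geometric end
            filaments.append(SlidingFilament(
                beads=beads, ring_id=ring, polarity=sense))
            # next filament starts before this one's geometric end
            arc = (n - 1) * L_Z
            th += (arc - overlaps[k]) / layout.ring_radius
    return filaments


# ---------------------------------------------------------------------------
# backbone elasticity

def _bond_arrays(filaments: list[SlidingFilament]):
    i, j = [], []
    for f in filaments:
        b = f.beads
        i.extend(b[:-1])
        j.extend(b[1:])
    return np.asarray(i, dtype=np.int64), np.asarray(j, dtype=np.int64)


def _angle_arrays(filaments: list[SlidingFilament]):
    i, j, k = [], [], []
    for f in filaments:
        b = f.beads
        if len(b) >= 3:
            i.extend(b[:-2]); j.extend(b[1:-1]); k.extend(b[2:])
    return (np.asarray(i, dtype=np.int64), np.asarray(j, dtype=np.int64),
            np.asarray(k, dtype=np.int64))


def hookean_forces(system: ParticleSystem, i, j, k_spring, l0) -> None:
    """Generic vectorized Hookean bond force (shared by several modules)."""
    if len(i) == 0:
        return
    vec = system.positions[j] - system.positions[i]
    d = row_norm(vec)
    d = np.maximum(d, MIN_DIST)
    u = vec / d[:, None]
    mag = k_spring * (d - l0)           # tension > 0 pulls ends together
    f = mag[:, None] * u
    scatter_add(system.forces, i, f)
    scatter_add(system.forces, j, -f)


def hookean_energy(system: ParticleSystem, i, j, k_spring, l0) -> float:
    if len(i) == 0:
        return 0.0
    d = row_norm(system.positions[j] - system.positions[i])
    return float(0.5 * np.sum(k_spring * (d - l0) ** 2))


def angle_bending_forces(system: ParticleSystem, i, j, k, k_theta,
                         theta0: float = 0.0) -> None:
    """Accumulate -∇ of E = k_theta (θ - θ0)²/2 at each interior bead j.

    Uses the exact angle gradient with a series-safe ``θ/sin θ`` factor so
    the straight (θ → 0) configuration is regular.
    """
    if len(i) == 0:
        return
    u = system.positions[i] - system.positions[j]
    v = system.positions[k] - system.positions[j]
    lu = row_norm(u)
    lv = row_norm(v)
    lu = np.maximum(lu, MIN_DIST)
    lv = np.maximum(lv, MIN_DIST)
    uh = u / lu[:, None]
    vh = v / lv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.clip(1.0 - c * c, 1e-24, None))
    # dE/dθ · dθ/d(cos θ) = -k(θ-θ0)/sin θ ; safe for θ0 = 0 as θ→0
    with np.errstate(invalid="ignore"):
        coef = np.where(s > 1e-8,
                        k_theta * (theta - theta0) / s,
                        k_theta * np.ones_like(s))  # limit (θ-0)/sinθ → 1
    # ∇_i cosθ = (vh - c uh)/lu ; ∇_k cosθ = (uh - c vh)/lv
    gi = (vh - c[:, None] * uh) / lu[:, None]
    gk = (uh - c[:, None] * vh) / lv[:, None]
    fi = coef[:, None] * gi          # F_i = -∇_i E = +coef ∇_i cosθ
    fk = coef[:, None] * gk
    scatter_add(system.forces, i, fi)
    scatter_add(system.forces, k, fk)
    scatter_add(system.forces, j, -(fi + fk))


def angle_bending_energy(system: ParticleSystem, i, j, k, k_theta,
                         theta0: float = 0.0) -> float:
    if len(i) == 0:
        return 0.0
    u = system.positions[i] - system.positions[j]
    v = system.positions[k] - system.positions[j]
    c = np.einsum("ij,ij->i", u, v) / (
        row_norm(u) * row_norm(v))
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    return float(0.5 * np.sum(k_theta * (theta - theta0) ** 2))


def backbone_forces(system: ParticleSystem, filaments: list[SlidingFilament]):
    f0 = filaments[0] if filaments else SlidingFilament(beads=[])
    bi, bj = _bond_arrays(filaments)
    hookean_forces(system, bi, bj, f0.k_z, f0.l_z)
    ai, aj, ak = _angle_arrays(filaments)
    angle_bending_forces(system, ai, aj, ak, f0.k_theta, f0.theta0)


def backbone_energy(system: ParticleSystem, filaments: list[SlidingFilament]):
    f0 = filaments[0] if filaments else SlidingFilament(beads=[])
    bi, bj = _bond_arrays(filaments)
    ai, aj, ak = _angle_arrays(filaments)
    return (hookean_energy(system, bi, bj, f0.k_z, f0.l_z)
            + angle_bending_energy(system, ai, aj, ak, f0.k_theta, f0.theta0))


# ---------------------------------------------------------------------------
# lateral Lennard-Jones interaction

def _interfilament_pairs(system: ParticleSystem, filaments, cutoff: float,
                         same_ring_only: bool | None = None):
    """Bead pairs on different filaments within ``cutoff``.

    ``same_ring_only``: if True keep same-ring pairs, if False keep
    different-ring pairs, if None keep all inter-filament pairs.
    """
    all_beads = np.concatenate([np.asarray(f.beads, dtype=np.int64)
                                for f in filaments]) if filaments else \
        np.empty(0, dtype=np.int64)
    if len(all_beads) == 0:
        return (np.empty(0, np.int64),) * 2
    owner = np.concatenate([np.full(f.n_beads, n, dtype=np.int64)
                            for n, f in enumerate(filaments)])
    ring = np.concatenate([np.full(f.n_beads, f.ring_id, dtype=np.int64)
                           for f in filaments])
    tree = cKDTree(system.positions[all_beads])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return (np.empty(0, np.int64),) * 2
    a, b = pairs[:, 0], pairs[:, 1]
    keep = owner[a] != owner[b]
    if same_ring_only is True:
        keep &= ring[a] == ring[b]
    elif same_ring_only is False:
        keep &= ring[a] != ring[b]
    return all_beads[a[keep]], all_beads[b[keep]]


def lj_force_magnitude(d: np.ndarray, eps: float = EPS,
                       rho: float = RHO) -> np.ndarray:
    """Pair force magnitude; positive = repulsive (pushes beads apart)."""
    x6 = (rho / d) ** 6
    return (24.0 * eps / d) * (2.0 * x6 * x6 - x6)


def lj_energy_pair(d: np.ndarray, eps: float = EPS,
                   rho: float = RHO) -> np.ndarray:
    x6 = (rho / d) ** 6
    return 4.0 * eps * (x6 * x6 - x6)


def lj_kernel(system: ParticleSystem, i, j, eps: float = EPS,
              rho: float = RHO, eps_scale=None, accumulate: bool = True,
              cutoff: float | None = None):
    """LJ pair kernel on precomputed pair arrays; returns energy if not
    accumulating.  ``eps_scale`` is an optional per-pair ε multiplier."""
    if cutoff is None:
        cutoff = LJ_CUTOFF_FACTOR * rho
    if len(i) == 0:
        return 0.0
    vec = system.positions[j] - system.positions[i]
    d = np.maximum(row_norm(vec), 0.3 * rho)  # clamp blowup
    act = d < cutoff
    if not act.any():
        return 0.0
    i, j, vec, d = i[act], j[act], vec[act], d[act]
    e = eps if eps_scale is None else eps * eps_scale[act]
    if not accumulate:
        x6 = (rho / d) ** 6
        return float(np.sum(4.0 * e * (x6 * x6 - x6)))
    u = vec / d[:, None]
    mag = (24.0 * e / d) * (2.0 * (rho / d) ** 12 - (rho / d) ** 6)
    f = -mag[:, None] * u   # positive magnitude pushes i away from j
    scatter_add(system.forces, i, f)
    scatter_add(system.forces, j, -f)
    return 0.0


def lj_forces(system: ParticleSystem, filaments, eps: float = EPS,
              rho: float = RHO) -> None:
    """Lennard-Jones forces between beads on different filaments."""
    i, j = _interfilament_pairs(system, filaments, LJ_CUTOFF_FACTOR * rho)
    lj_kernel(system, i, j, eps, rho, accumulate=True)


def lj_energy(system: ParticleSystem, filaments, eps: float = EPS,
              rho: float = RHO) -> float:
    i, j = _interfilament_pairs(system, filaments, LJ_CUTOFF_FACTOR * rho)
    return lj_kernel(system, i, j, eps, rho, accumulate=False)


def ring_sep_kernel(system: ParticleSystem, i, j, d_s: float = D_S,
                    k_s: float = K_S, accumulate: bool = True):
    """Different-ring repulsion kernel on precomputed pair arrays."""
    if len(i) == 0:
        return 0.0
    vec = system.positions[j] - system.positions[i]
    d = np.maximum(row_norm(vec), MIN_DIST)
    act = d < d_s
    if not act.any():
        return 0.0
    i, j, vec, d = i[act], j[act], vec[act], d[act]
    if not accumulate:
        return float(0.5 * k_s * np.sum((d_s - d) ** 2))
    u = vec / d[:, None]
    f = -(k_s * (d_s - d))[:, None] * u
    scatter_add(system.forces, i, f)
    scatter_add(system.forces, j, -f)
    return 0.0


def ring_separation_forces(system: ParticleSystem, filaments,
                           d_s: float = D_S, k_s: float = K_S) -> None:
    """Repulsion between beads on *different* rings below ``d_s``."""
    i, j = _interfilament_pairs(system, filaments, d_s, same_ring_only=False)
    ring_sep_kernel(system, i, j, d_s, k_s, accumulate=True)


def ring_separation_energy(system: ParticleSystem, filaments,
                           d_s: float = D_S, k_s: float = K_S) -> float:
    i, j = _interfilament_pairs(system, filaments, d_s, same_ring_only=False)
    return ring_sep_kernel(system, i, j, d_s, k_s, accumulate=False)


# ---------------------------------------------------------------------------
# remodeling: depolymerization and treadmilling

def remodel_step(system: ParticleSystem, filaments: list[SlidingFilament],
                 mode: str, n_events_per_filament) -> list[SlidingFilament]:
    """Apply bead-level remodeling events.

    ``mode``: ``"depolymerize"`` removes beads from the minus end;
    ``"treadmill"`` additionally appends a bead at the plus end per event
    (placed along the terminal bond direction at spacing ``l_z``).
    Filaments shrinking below two beads are dropped.  Event counts are
    supplied by the scheduler (deterministic or Poisson clock).
    """
    survivors = []
    for f, n_ev in zip(filaments, n_events_per_filament):
        for _ in range(int(n_ev)):
            if mode == "treadmill" and f.n_beads >= 2:
                p_last = system.positions[f.beads[-1]]
                p_prev = system.positions[f.beads[-2]]
                u = p_last - p_prev
                nrm = row_norm(u)
                u = u / nrm if nrm > MIN_DIST else np.array([0.0, 0.0, 1.0])
                new = system.add_beads((p_last + f.l_z * u)[None, :], FTSZ)
                f.beads.append(int(new[0]))
            if f.n_beads > 0:
                gone = f.beads.pop(0)
                system.mobile[gone] = False
                system.positions[gone] = 1e6  # park far away, excluded from lists
        if f.n_beads >= 2:
            survivors.append(f)
        else:
            log.info("filament dropped (fewer than 2 beads)")
            for b in f.beads:
                system.mobile[b] = False
                system.positions[b] = 1e6
    return survivors


# ---------------------------------------------------------------------------
# lateral free-energy-vs-overlap profile

def lateral_energy_profile(n_a: int = 40, n_b: int = 40,
                           shift_grid: np.ndarray | None = None,
                           eps: float = EPS, rho: float = RHO,
                           l_z: float = L_Z):
    """Total LJ energy of two straight parallel chains vs registry shift.

    Chains sit at lateral distance ``2^(1/6) ρ`` (the pair-potential
    minimum).  Returns ``(shifts, energies)``.  In-register states
    (shift = multiple of ``l_z``) are local minima whose depth grows
    linearly with overlap, and the barrier between adjacent minima grows
    with overlap length — the avidity that arrests sliding.
    """
    if shift_grid is None:
        shift_grid = np.linspace(-1.0, (n_a + 2) * l_z, 600)
    xa = np.arange(n_a) * l_z
    gap = 2.0 ** (1.0 / 6.0) * rho
    energies = np.empty(len(shift_grid))
    xb0 = -(n_b - 1) * l_z  # start fully disengaged below chain a
    for n, s in enumerate(shift_grid):
        xb = xb0 + s + np.arange(n_b) * l_z
        dx = xa[:, None] - xb[None, :]
        d = np.sqrt(dx * dx + gap * gap)
        d = d[d < LJ_CUTOFF_FACTOR * rho]
        energies[n] = np.sum(lj_energy_pair(d, eps, rho))
    return shift_grid, energies


def overlap_barrier(overlap_beads: int, eps: float = EPS, rho: float = RHO,
                    l_z: float = L_Z) -> float:
    """Energy barrier between adjacent in-register states at a given overlap.

    The profile over one subunit of shift superposes a monotone zipper
    tilt (overlap keeps growing) on the registry corrugation; the cost of
    breaking the lateral bonds to pass through the off-register
    intermediate is the *detrended* oscillation amplitude, which grows
    with the number of lateral bonds — the avidity that arrests sliding.
    """
    n = max(overlap_beads + 4, 8)
    # at shift s the overlap is 1 + s/l_z beads (chains start touching at s=0)
    base = (overlap_beads - 1) * l_z
    shifts = base + np.linspace(0.0, l_z, 41)
    _, e = lateral_energy_profile(n, n, shifts, eps, rho, l_z)
    detrended = e - np.polyval(np.polyfit(shifts, e, 1), shifts)
    return float(detrended.max() - detrended.min())
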