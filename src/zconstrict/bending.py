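"""Cube-chain FtsZ filaments for the filament-bending hypothesis.

Each monomer is a cube of edge ``l_z`` = 4.4 nm; adjacent cubes share a
face, so a filament of ``n`` monomers has ``n + 1`` four-bead
cross-sections (``4(n+1)`` unique beads).  Within cube ``i`` the beads
follow the labelling

* cross-sections {1,2,3,4} and {5,6,7,8}; beads 5–8 of cube ``i`` are
  beads 1–4 of cube ``i+1``,
* the C-terminal (membrane-facing) face is {1,2,6,5}; the N-terminal
  face is {4,3,7,8}.

Elasticity:

* the four edges of every cross-section square: springs (``k_z``,
  ``l_z``) maintaining filament width,
* per junction, two edge-midpoint springs (edge 1-4 ↔ 5-8 and 2-3 ↔
  6-7; ``k_z``, ``l_z``) maintaining filament length,
* per junction, two C-face springs (1–5, 2–6; relaxed ``l_C``) and two
  N-face springs (3–7, 4–8; relaxed ``l_N``) with constant ``k_b``:
  GTP-state (straight) filaments have ``l_C = l_N = l_0``; after GTP
  hydrolysis (bent) ``l_C = l_0 + Δl_0`` and ``l_N = l_0 - Δl_0`` with
  ``Δl_0 = l_z sin(θ_b/2)``; *reverse* bending swaps the two.  ``l_0``
  is the live distance between the two cross-section centres, not a
  frozen constant,
* anti-twist: on every cube face, a restoring force ``k_z Δl`` (half
  per bead) equalizes the two diagonals.

The preferred bend angle relates to the diameter of the circle a free
filament closes: ``θ_b = 360 l_z / (π · diameter)`` degrees (250 nm ↔
2°, 50 nm ↔ 10°).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .system import cross3, row_norm, ParticleSystem, FTSZ, scatter_add
from .sliding import hookean_forces, hookean_energy, MIN_DIST

log = logging.getLogger(__name__)

L_Z = 4.4
K_Z = 500.0
K_THETA = 3800.0
K_DP = 20.0       # pN/nm, division-plane restoring constant
D_ZZ = 6.5        # nm, cube-centre exclusion onset
K_ZZ = 1000.0     # pN/nm (1 nN/nm)

STRAIGHT, BENT, REVERSE_BENT = "straight", "bent", "reverse_bent"


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction u to direction v (Rodrigues)."""
    un = u / max(np.linalg.norm(u), MIN_DIST)
    vn = v / max(np.linalg.norm(v), MIN_DIST)
    axis = np.cross(un, vn)
    s = np.linalg.norm(axis)
    c = float(un @ vn)
    if s < 1e-12:
        return np.eye(3)
    axis = axis / s
    kmat = np.array([[0.0, -axis[2], axis[1]],
                     [axis[2], 0.0, -axis[0]],
                     [-axis[1], axis[0], 0.0]])
    return np.eye(3) + s * kmat + (1.0 - c) * (kmat @ kmat)


def theta_from_diameter(diameter: float, l_z: float = L_Z) -> float:
    """Preferred inter-monomer angle (degrees) closing a circle of ``diameter``.

    A closed circle of ``N`` subunits spaced ``l_z`` turns 360° in total,
    so each interface turns ``360/N`` with ``N = π·diameter/l_z``.
    """
    if diameter <= 2 * l_z / np.pi:
        raise ValueError("diameter too small for the subunit spacing")
    return 360.0 * l_z / (np.pi * diameter)


def diameter_from_theta(theta_b_deg: float, l_z: float = L_Z) -> float:
    """Inverse of :func:`theta_from_diameter`."""
    return 360.0 * l_z / (np.pi * theta_b_deg)


def delta_l0(theta_b_deg: float, l_z: float = L_Z) -> float:
    """Relaxed-length offset Δl_0 = l_z sin(θ_b/2)."""
    return l_z * np.sin(np.deg2rad(theta_b_deg) / 2.0)


def kb_from_eq2(theta_b_rad: float, k_theta: float = K_THETA,
                l_z: float = L_Z) -> float:
    """Bending-spring constant from energy matching.

    The energy stored in the four face springs deformed by Δl_0,
    ``4·(k_b Δl_0²/2)``, is set equal to the harmonic bending energy
    ``k_θ θ_b²/2`` of one interface, giving
    ``k_b = k_θ θ_b² / (4 Δl_0²)``.
    """
    if theta_b_rad <= 0:
        raise ValueError("theta_b must be positive")
    dl = l_z * np.sin(theta_b_rad / 2.0)
    return k_theta * theta_b_rad ** 2 / (4.0 * dl ** 2)


@dataclass
class CubeFilament:
    """Chain of shared-face monomer cubes.

    ``cross_sections[j]`` holds the four system bead indices of
    cross-section ``j`` in label order [1, 2, 3, 4] (1, 2 on the C side;
    edge 1-4 and 2-3 are the division-plane-constrained edges).  The
    minus end is cross-section 0.
    """
    cross_sections: list[list[int]]
    state: str = STRAIGHT
    theta_b_deg: float = 10.0
    k_b: float = 0.0
    l_z: float = L_Z
    k_z: float = K_Z
    ring_id: int = 0
    polarity: int = 1

    @property
    def n_monomers(self) -> int:
        return len(self.cross_sections) - 1

    @property
    def all_beads(self) -> np.ndarray:
        return np.asarray(self.cross_sections, dtype=np.int64).ravel()

    @property
    def dl0(self) -> float:
        if self.state == STRAIGHT:
            return 0.0
        sign = 1.0 if self.state == BENT else -1.0
        return sign * delta_l0(self.theta_b_deg, self.l_z)

    def centers(self, system: ParticleSystem) -> np.ndarray:
        """Cross-section centres, shape (n+1, 3)."""
        cs = np.asarray(self.cross_sections, dtype=np.int64)
        return system.positions[cs].mean(axis=1)

    def cube_centers(self, system: ParticleSystem) -> np.ndarray:
        c = self.centers(system)
        return 0.5 * (c[:-1] + c[1:])


def set_bending_state(f: CubeFilament, state: str,
                      theta_b_deg: float | None = None,
                      k_theta: float = K_THETA) -> None:
    """Switch nucleotide/bending state and update ``k_b``.

    ``l_0`` is never frozen — it is measured from the live geometry at
    every force evaluation — so only the state tag, θ_b and ``k_b``
    change here.
    """
    if state not in (STRAIGHT, BENT, REVERSE_BENT):
        raise ValueError(f"unknown state {state!r}")
    f.state = state
    if theta_b_deg is not None:
        f.theta_b_deg = theta_b_deg
    f.k_b = kb_from_eq2(np.deg2rad(f.theta_b_deg), k_theta, f.l_z)


# ---------------------------------------------------------------------------
# construction

def _frame_corners(center, rhat, xhat, l_z):
    """Corner offsets for one cross-section in label order [1, 2, 3, 4].

    C side (labels 1, 2) along +rhat (toward the membrane); labels 1 and
    4 share the +xhat side so edges 1-4 and 2-3 lie along rhat.
    """
    h = l_z / 2.0
    return np.array([
        center + h * (rhat + xhat),   # 1  C, +x
        center + h * (rhat - xhat),   # 2  C, -x
        center + h * (-rhat - xhat),  # 3  N, -x
        center + h * (-rhat + xhat),  # 4  N, +x
    ])


def build_cube_filament(system: ParticleSystem, n_monomers: int,
                        ring_radius: float, center_x: float,
                        theta_start: float = 0.0, sense: int = 1,
                        l_z: float = L_Z, ring_id: int = 0,
                        tilt_deg: float = 0.0,
                        **kw) -> CubeFilament:
    """Build a straight-state filament along a circular arc.

    The arc lies in the plane ``x = center_x`` on a circle of
    ``ring_radius`` about the long axis; the C-face points radially
    outward (toward the membrane).  ``tilt_deg`` rotates the cube frame
    about the filament axis, tipping the bending plane out of the
    division plane (used to probe the rolling instability).
    """
    if n_monomers < 2:
        raise ValueError("a cube filament needs at least 2 monomers")
    dth = sense * l_z / ring_radius
    phi = np.deg2rad(tilt_deg)
    cs = []
    for j in range(n_monomers + 1):
        th = theta_start + j * dth
        rhat = np.array([0.0, np.cos(th), np.sin(th)])
        xhat = np.array([1.0, 0.0, 0.0])
        center = np.array([center_x, 0.0, 0.0]) + ring_radius * rhat
        rh = np.cos(phi) * rhat + np.sin(phi) * xhat
        xh = -np.sin(phi) * rhat + np.cos(phi) * xhat
        corners = _frame_corners(center, rh, xh, l_z)
        idx = system.add_beads(corners, FTSZ)
        cs.append([int(i) for i in idx])
    return CubeFilament(cross_sections=cs, l_z=l_z, ring_id=ring_id,
                        polarity=sense, **kw)


def build_straight_cube_filament(system: ParticleSystem, n_monomers: int,
                                 origin=(0.0, 0.0, 0.0),
                                 axis=(0.0, 0.0, 1.0),
                                 c_dir=(0.0, 1.0, 0.0),
                                 l_z: float = L_Z, **kw) -> CubeFilament:
    """Build a relaxed straight filament along ``axis`` (for tests/fixtures)."""
    if n_monomers < 2:
        raise ValueError("a cube filament needs at least 2 monomers")
    t = np.asarray(axis, float); t /= row_norm(t)
    r = np.asarray(c_dir, float); r -= (r @ t) * t; r /= row_norm(r)
    x = cross3(r, t)
    cs = []
    for j in range(n_monomers + 1):
        center = np.asarray(origin, float) + j * l_z * t
        idx = system.add_beads(_frame_corners(center, r, x, l_z), FTSZ)
        cs.append([int(i) for i in idx])
    return CubeFilament(cross_sections=cs, l_z=l_z, **kw)


# ---------------------------------------------------------------------------
# elasticity

def _midpoint_spring(system, a1, a2, b1, b2, k, l0, accumulate: bool):
    """Spring between edge midpoints (a1,a2) and (b1,b2); returns energy."""
    pa = 0.5 * (system.positions[a1] + system.positions[a2])
    pb = 0.5 * (system.positions[b1] + system.positions[b2])
    vec = pb - pa
    d = np.maximum(row_norm(vec), MIN_DIST)
    if accumulate:
        u = vec / d[:, None]
        f = (k * (d - l0))[:, None] * u   # pulls midpoints together if stretched
        for a in (a1, a2):
            scatter_add(system.forces, a, 0.5 * f)
        for b in (b1, b2):
            scatter_add(system.forces, b, -0.5 * f)
        return 0.0
    return float(0.5 * k * np.sum((d - l0) ** 2))


def _diag_equalizer(system, d1a, d1c, d2b, d2d, k, accumulate: bool):
    """Anti-twist: equalize the lengths of face diagonals (d1a-d1c, d2b-d2d).

    Energy ``(k/4)(l1 - l2)²`` so each bead feels magnitude ``k|Δl|/2``.
    """
    v1 = system.positions[d1c] - system.positions[d1a]
    v2 = system.positions[d2d] - system.positions[d2b]
    l1 = np.maximum(row_norm(v1), MIN_DIST)
    l2 = np.maximum(row_norm(v2), MIN_DIST)
    if not accumulate:
        return float(0.25 * k * np.sum((l1 - l2) ** 2))
    u1 = v1 / l1[:, None]
    u2 = v2 / l2[:, None]
    coef = 0.5 * k * (l1 - l2)
    # dE/dl1 = +k/2 (l1-l2); force shortens the longer diagonal
    scatter_add(system.forces, d1a, coef[:, None] * u1)
    scatter_add(system.forces, d1c, -coef[:, None] * u1)
    scatter_add(system.forces, d2b, -coef[:, None] * u2)
    scatter_add(system.forces, d2d, coef[:, None] * u2)
    return 0.0


def _bending_springs(system, f: CubeFilament, accumulate: bool) -> float:
    """C/N face springs with live relaxed lengths l_0 ± Δl_0.

    The gradient includes the dependence of ``l_0`` (centre–centre
    distance) on all eight junction beads, so forces are the exact
    negative gradient of the energy.
    """
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    a, b = cs[:-1], cs[1:]                     # labels 1-4, labels 5-8
    pa = system.positions[a]                   # (n, 4, 3)
    pb = system.positions[b]
    c1 = pa.mean(axis=1)
    c2 = pb.mean(axis=1)
    v0 = c2 - c1
    l0 = np.maximum(row_norm(v0), MIN_DIST)
    u0 = v0 / l0[:, None]
    dl = f.dl0
    energy = 0.0
    # springs: (label-1 -> label-5, +dl), (2 -> 6, +dl), (3 -> 7, -dl), (4 -> 8, -dl)
    residual_sum = np.zeros(len(l0))
    for col, sgn in ((0, 1.0), (1, 1.0), (2, -1.0), (3, -1.0)):
        vec = pb[:, col] - pa[:, col]
        d = np.maximum(row_norm(vec), MIN_DIST)
        target = l0 + sgn * dl
        if accumulate:
            u = vec / d[:, None]
            tension = f.k_b * (d - target)
            fv = tension[:, None] * u
            scatter_add(system.forces, a[:, col], fv)
            scatter_add(system.forces, b[:, col], -fv)
            residual_sum += tension
        else:
            energy += float(0.5 * f.k_b * np.sum((d - target) ** 2))
    if accumulate:
        # chain-rule term from l_0(positions): dE/dl0 = -Σ tension
        # ∂l0/∂(face-1 bead) = -u0/4, ∂l0/∂(face-2 bead) = +u0/4
        g = (residual_sum[:, None] * u0) / 4.0
        for col in range(4):
            scatter_add(system.forces, a[:, col], -g)
            scatter_add(system.forces, b[:, col], g)
    return energy


def _cube_faces(f: CubeFilament):
    """Diagonal index arrays for all unique faces (for anti-twist)."""
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    d1a, d1c, d2b, d2d = [], [], [], []
    # cross-sectional faces: diagonals (1,3) and (2,4)
    d1a.append(cs[:, 0]); d1c.append(cs[:, 2])
    d2b.append(cs[:, 1]); d2d.append(cs[:, 3])
    a, b = cs[:-1], cs[1:]
    # C-face {1,2,6,5}: diagonals (1,6), (2,5)
    d1a.append(a[:, 0]); d1c.append(b[:, 1])
    d2b.append(a[:, 1]); d2d.append(b[:, 0])
    # N-face {4,3,7,8}: diagonals (4,7), (3,8)
    d1a.append(a[:, 3]); d1c.append(b[:, 2])
    d2b.append(a[:, 2]); d2d.append(b[:, 3])
    # side faces {1,4,8,5}: diagonals (1,8), (4,5); {2,3,7,6}: (2,7), (3,6)
    d1a.append(a[:, 0]); d1c.append(b[:, 3])
    d2b.append(a[:, 3]); d2d.append(b[:, 0])
    d1a.append(a[:, 1]); d1c.append(b[:, 2])
    d2b.append(a[:, 2]); d2d.append(b[:, 1])
    cat = lambda lst: np.concatenate(lst)
    return cat(d1a), cat(d1c), cat(d2b), cat(d2d)


def _edge_springs(f: CubeFilament):
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    # cross-section square edges 1-2, 2-3, 3-4, 4-1
    i = np.concatenate([cs[:, 0], cs[:, 1], cs[:, 2], cs[:, 3]])
    j = np.concatenate([cs[:, 1], cs[:, 2], cs[:, 3], cs[:, 0]])
    return i, j


def cube_elastic_forces(system: ParticleSystem, f: CubeFilament) -> None:
    _cube_elastic(system, f, accumulate=True)


def cube_elastic_energy(system: ParticleSystem, f: CubeFilament) -> float:
    return _cube_elastic(system, f, accumulate=False)


def _cube_elastic(system: ParticleSystem, f: CubeFilament, accumulate: bool):
    ei, ej = _edge_springs(f)
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    a, b = cs[:-1], cs[1:]
    e = 0.0
    if accumulate:
        hookean_forces(system, ei, ej, f.k_z, f.l_z)
    else:
        e += hookean_energy(system, ei, ej, f.k_z, f.l_z)
    # junction length-keeping springs between edge midpoints
    e += _midpoint_spring(system, a[:, 0], a[:, 3], b[:, 0], b[:, 3],
                          f.k_z, f.l_z, accumulate)
    e += _midpoint_spring(system, a[:, 1], a[:, 2], b[:, 1], b[:, 2],
                          f.k_z, f.l_z, accumulate)
    e += _bending_springs(system, f, accumulate)
    e += _diag_equalizer(system, *_cube_faces(f), f.k_z, accumulate)
    return e


# ---------------------------------------------------------------------------
# division-plane confinement (rigid-linker scenario)

def division_plane_forces(system: ParticleSystem, f: CubeFilament,
                          k_dp: float = K_DP) -> None:
    """Keep the radial cube edges parallel to the division plane.

    For every constrained edge (1-4 and 2-3 of each cross-section) with
    long-axis projection ``d``, both end beads receive a restoring force
    ``k_dp·d`` nulling the projection.
    """
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    for c0, c1 in ((0, 3), (1, 2)):
        i, j = cs[:, c0], cs[:, c1]
        dx = system.positions[j, 0] - system.positions[i, 0]
        fx = k_dp * dx
        system.forces[:, 0] += np.bincount(i, weights=fx,
                                           minlength=system.n_beads)
        system.forces[:, 0] += np.bincount(j, weights=-fx,
                                           minlength=system.n_beads)


def division_plane_energy(system: ParticleSystem, f: CubeFilament,
                          k_dp: float = K_DP) -> float:
    cs = np.asarray(f.cross_sections, dtype=np.int64)
    e = 0.0
    for c0, c1 in ((0, 3), (1, 2)):
        dx = system.positions[cs[:, c1], 0] - system.positions[cs[:, c0], 0]
        e += float(0.5 * k_dp * np.sum(dx ** 2))
    return e


# ---------------------------------------------------------------------------
# treadmilling

def treadmill_cube_step(system: ParticleSystem, f: CubeFilament,
                        n_events: int) -> CubeFilament | None:
    """Per event: append one cube at the plus end, drop one at the minus end.

    The new cross-section copies the terminal cross-section translated by
    the last centre-to-centre vector (the terminal cube's local frame),
    inheriting the bending state.  Returns None if the filament falls
    below 2 monomers.
    """
    for _ in range(int(n_events)):
        if f.n_monomers < 2:
            break
        cs_last = np.asarray(f.cross_sections[-1], dtype=np.int64)
        cs_prev = np.asarray(f.cross_sections[-2], dtype=np.int64)
        c_last = system.positions[cs_last].mean(axis=0)
        c_prev = system.positions[cs_prev].mean(axis=0)
        shift = c_last - c_prev
        if f.n_monomers >= 2:
            # continue the filament's current arc: rotate the terminal
            # segment by the turn between the last two segments
            cs_pp = np.asarray(f.cross_sections[-3], dtype=np.int64)
            u = c_prev - system.positions[cs_pp].mean(axis=0)
            rot = _rotation_between(u, shift)
            shift = rot @ shift
            new_pts = c_last + (rot @ (system.positions[cs_last]
                                       - c_last).T).T + shift
        else:
            new_pts = system.positions[cs_last] + shift
        idx = system.add_beads(new_pts, FTSZ)
        f.cross_sections.append([int(i) for i in idx])
        gone = f.cross_sections.pop(0)
        for bead in gone:
            system.mobile[bead] = False
            system.positions[bead] = 1e6
    if f.n_monomers < 2:
        log.info("cube filament dropped (fewer than 2 monomers)")
        for cs_ in f.cross_sections:
            for bead in cs_:
                system.mobile[bead] = False
                system.positions[bead] = 1e6
        return None
    return f


# ---------------------------------------------------------------------------
# cube-cube volume exclusion (bending model)

def cube_exclusion_forces(system: ParticleSystem,
                          filaments: list[CubeFilament],
                          d_zz: float = D_ZZ, k_zz: float = K_ZZ) -> None:
    """Repulsion between cube centres of different filaments below ``d_zz``.

    The force magnitude ``k_zz (d_zz - d)`` acts on *each* bead of both
    cubes (energy ``4 k_zz (d_zz - d)²``, distributed by the exact
    gradient through the centre positions).
    """
    _cube_exclusion(system, filaments, d_zz, k_zz, accumulate=True)


def cube_exclusion_energy(system: ParticleSystem,
                          filaments: list[CubeFilament],
                          d_zz: float = D_ZZ, k_zz: float = K_ZZ) -> float:
    return _cube_exclusion(system, filaments, d_zz, k_zz, accumulate=False)


def cube_pair_candidates(system, filaments: list[CubeFilament],
                         cutoff: float):
    """Cube pairs (of different filaments) with centres within ``cutoff``.

    Returns ``(a8, b8)``: the (P, 8) bead-index arrays of the two cubes
    of each candidate pair, for use with :func:`cube_exclusion_kernel`.
    """
    from scipy.spatial import cKDTree
    if len(filaments) < 2:
        return (np.empty((0, 8), np.int64),) * 2
    centers, owner, bead_sets = [], [], []
    for n, f in enumerate(filaments):
        cc = f.cube_centers(system)
        centers.append(cc)
        owner.append(np.full(len(cc), n))
        cs = np.asarray(f.cross_sections, dtype=np.int64)
        bead_sets.append(np.concatenate([cs[:-1], cs[1:]], axis=1))  # (n,8)
    centers = np.vstack(centers)
    owner = np.concatenate(owner)
    beads8 = np.vstack(bead_sets)
    tree = cKDTree(centers)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return (np.empty((0, 8), np.int64),) * 2
    a, b = pairs[:, 0], pairs[:, 1]
    keep = owner[a] != owner[b]
    return beads8[a[keep]], beads8[b[keep]]


def cube_exclusion_kernel(system, a8, b8, d_zz: float = D_ZZ,
                          k_zz: float = K_ZZ, accumulate: bool = True):
    """Centre-centre repulsion on precomputed cube pairs.

    Energy ``4 k_zz (d_zz - d)²`` per active pair; via the centre chain
    rule each of the 8 beads of both cubes feels magnitude
    ``k_zz (d_zz - d)``, as specified.
    """
    if len(a8) == 0:
        return 0.0
    ca = system.positions[a8].mean(axis=1)
    cb = system.positions[b8].mean(axis=1)
    vec = cb - ca
    d = np.maximum(row_norm(vec), MIN_DIST)
    act = d < d_zz
    if not act.any():
        return 0.0
    a8, b8, vec, d = a8[act], b8[act], vec[act], d[act]
    if not accumulate:
        return float(4.0 * k_zz * np.sum((d_zz - d) ** 2))
    u = vec / d[:, None]
    fv = -(k_zz * (d_zz - d))[:, None] * u    # per-bead contribution
    for col in range(8):
        scatter_add(system.forces, a8[:, col], fv)
        scatter_add(system.forces, b8[:, col], -fv)
    return 0.0


def _cube_exclusion(system, filaments, d_zz, k_zz, accumulate):
    a8, b8 = cube_pair_candidates(system, filaments, d_zz)
    return cube_exclusion_kernel(system, a8, b8, d_zz, k_zz, accumulate)


# ---------------------------------------------------------------------------
# batched evaluation (all cube filaments in one pass)

@dataclass
class CubeBatch:
    """Concatenated spring index arrays for a set of cube filaments.

    Rebuilt whenever filament composition changes (remodeling); lets the
    integrator evaluate all cube elasticity with a single force scatter.
    """
    edge_i: np.ndarray
    edge_j: np.ndarray
    mid_a1: np.ndarray
    mid_a2: np.ndarray
    mid_b1: np.ndarray
    mid_b2: np.ndarray
    bend_a: np.ndarray          # (J, 4) labels 1-4
    bend_b: np.ndarray          # (J, 4) labels 5-8
    k_b: np.ndarray             # (J,)
    dl0: np.ndarray             # (J,)
    d1a: np.ndarray
    d1c: np.ndarray
    d2b: np.ndarray
    d2d: np.ndarray
    dp_i: np.ndarray            # division-plane constrained edge ends
    dp_j: np.ndarray
    k_z: float = K_Z
    l_z: float = L_Z


def cube_batch(filaments: list[CubeFilament]) -> CubeBatch | None:
    if not filaments:
        return None
    cols = {k: [] for k in ("ei", "ej", "ma1", "ma2", "mb1", "mb2",
                            "ba", "bb", "kb", "dl", "d1a", "d1c", "d2b",
                            "d2d", "dpi", "dpj")}
    for f in filaments:
        cs = np.asarray(f.cross_sections, dtype=np.int64)
        a, b = cs[:-1], cs[1:]
        ei, ej = _edge_springs(f)
        cols["ei"].append(ei); cols["ej"].append(ej)
        cols["ma1"].append(a[:, 0]); cols["ma2"].append(a[:, 3])
        cols["mb1"].append(b[:, 0]); cols["mb2"].append(b[:, 3])
        cols["ma1"].append(a[:, 1]); cols["ma2"].append(a[:, 2])
        cols["mb1"].append(b[:, 1]); cols["mb2"].append(b[:, 2])
        cols["ba"].append(a); cols["bb"].append(b)
        cols["kb"].append(np.full(len(a), f.k_b))
        cols["dl"].append(np.full(len(a), f.dl0))
        q = _cube_faces(f)
        cols["d1a"].append(q[0]); cols["d1c"].append(q[1])
        cols["d2b"].append(q[2]); cols["d2d"].append(q[3])
        for c0, c1 in ((0, 3), (1, 2)):
            cols["dpi"].append(cs[:, c0]); cols["dpj"].append(cs[:, c1])
    cat = np.concatenate
    return CubeBatch(
        edge_i=cat(cols["ei"]), edge_j=cat(cols["ej"]),
        mid_a1=cat(cols["ma1"]), mid_a2=cat(cols["ma2"]),
        mid_b1=cat(cols["mb1"]), mid_b2=cat(cols["mb2"]),
        bend_a=np.vstack(cols["ba"]), bend_b=np.vstack(cols["bb"]),
        k_b=cat(cols["kb"]), dl0=cat(cols["dl"]),
        d1a=cat(cols["d1a"]), d1c=cat(cols["d1c"]),
        d2b=cat(cols["d2b"]), d2d=cat(cols["d2d"]),
        dp_i=cat(cols["dpi"]), dp_j=cat(cols["dpj"]),
        k_z=filaments[0].k_z, l_z=filaments[0].l_z)


def cube_batch_forces(system: ParticleSystem, batch: CubeBatch,
                      division_plane: bool = False,
                      k_dp: float = K_DP) -> None:
    """All cube elastic (+ optional division-plane) forces, one scatter."""
    if batch is None:
        return
    pos = system.positions
    idx_out, f_out = [], []

    def emit(idx, f):
        idx_out.append(idx)
        f_out.append(f)

    # cross-section edge springs
    vec = pos[batch.edge_j] - pos[batch.edge_i]
    d = np.maximum(row_norm(vec), MIN_DIST)
    f = (batch.k_z * (d - batch.l_z) / d)[:, None] * vec
    emit(batch.edge_i, f); emit(batch.edge_j, -f)
    # junction midpoint springs
    pa = 0.5 * (pos[batch.mid_a1] + pos[batch.mid_a2])
    pb = 0.5 * (pos[batch.mid_b1] + pos[batch.mid_b2])
    vec = pb - pa
    d = np.maximum(row_norm(vec), MIN_DIST)
    f = (batch.k_z * (d - batch.l_z) / d)[:, None] * vec
    emit(batch.mid_a1, 0.5 * f); emit(batch.mid_a2, 0.5 * f)
    emit(batch.mid_b1, -0.5 * f); emit(batch.mid_b2, -0.5 * f)
    # bending springs with live l_0
    a, b = batch.bend_a, batch.bend_b
    pa4 = pos[a]
    pb4 = pos[b]
    c1 = pa4.mean(axis=1)
    c2 = pb4.mean(axis=1)
    v0 = c2 - c1
    l0 = np.maximum(row_norm(v0), MIN_DIST)
    u0 = v0 / l0[:, None]
    residual = np.zeros(len(l0))
    for col, sgn in ((0, 1.0), (1, 1.0), (2, -1.0), (3, -1.0)):
        vec = pb4[:, col] - pa4[:, col]
        d = np.maximum(row_norm(vec), MIN_DIST)
        tension = batch.k_b * (d - (l0 + sgn * batch.dl0))
        fv = (tension / d)[:, None] * vec
        emit(a[:, col], fv); emit(b[:, col], -fv)
        residual += tension
    g = (residual[:, None] * u0) / 4.0
    for col in range(4):
        emit(a[:, col], -g); emit(b[:, col], g)
    # anti-twist diagonal equalizers
    v1 = pos[batch.d1c] - pos[batch.d1a]
    v2 = pos[batch.d2d] - pos[batch.d2b]
    l1 = np.maximum(row_norm(v1), MIN_DIST)
    l2 = np.maximum(row_norm(v2), MIN_DIST)
    coef = 0.5 * batch.k_z * (l1 - l2)
    u1 = (coef / l1)[:, None] * v1
    u2 = (coef / l2)[:, None] * v2
    emit(batch.d1a, u1); emit(batch.d1c, -u1)
    emit(batch.d2b, -u2); emit(batch.d2d, u2)
    # division-plane confinement
    if division_plane:
        dx = pos[batch.dp_j, 0] - pos[batch.dp_i, 0]
        fx = np.zeros((len(dx), 3))
        fx[:, 0] = k_dp * dx
        emit(batch.dp_i, fx); emit(batch.dp_j, -fx)

    scatter_add(system.forces, np.concatenate(idx_out),
                np.concatenate(f_out))
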