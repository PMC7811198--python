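"""Turgor-pressurized peptidoglycan cell wall as a hoop-grid of beads.

The wall is a cylinder of bead hoops (default 11 hoops of 104 beads,
radius 265 nm) outside the membrane.  Circumferential *glycan* springs
(``k_g`` = 100 pN/nm) carry dynamic relaxed lengths ``l_g``; axial
*peptide* springs (``k_p`` = 10 pN/nm, ``l_p`` = 16 nm) tie the hoops
together.  ``l_g`` is initialized so that 1 atm of turgor stretches
every glycan spring to 16 nm::

    l_g = l_ext - (P_tg · r_g / k_g) · l_p

Turgor acts as the gradient of the enclosed volume: the lateral surface
is triangulated, each triangle plus the wall centroid forms a
tetrahedron, and each bead feels ``F_j = P_tg Σ ∇_j V_i`` (outward).

The two outermost hoops are translational images of each other
(periodic boundary): the last hoop carries no glycan springs of its own
and the per-bead forces of the two edge hoops are summed and applied to
both, which keeps them congruent.

The membrane is held 15 nm inside the local wall surface by a squeeze
force ``F_w = k_w Δd²`` (``k_w`` = 1.6 pN/nm²); wall growth shortens the
glycan relaxed lengths wherever the membrane has pulled away, letting
the wall follow the constricting membrane inward at a bounded rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import cross3, row_norm, ParticleSystem, WALL, scatter_add
from .sliding import hookean_forces, hookean_energy, MIN_DIST
from .units import atmospheres

log = logging.getLogger(__name__)

K_G = 100.0
K_P = 10.0
L_EXT = 16.0
K_W = 1.6       # pN/nm^2, membrane-wall squeeze
D_WM = 15.0     # nm, equilibrium membrane-wall gap
P_TG = atmospheres(1.0)
L_G_FLOOR = 1e-3


def initial_glycan_length(l_ext: float = L_EXT, p_tg: float = P_TG,
                          r_g: float = 265.0, k_g: float = K_G,
                          l_p: float = L_EXT) -> float:
    """Relaxed glycan length such that turgor stretches springs to ``l_ext``."""
    l_g = l_ext - (p_tg * r_g / k_g) * l_p
    if l_g <= 0:
        raise ValueError("non-positive glycan relaxed length")
    return l_g


@dataclass
class WallGrowthPolicy:
    nu_w: float = 100.0              # nm/s, inward growth-rate limit
    gap_trigger: float = 0.5         # nm beyond d_w-m that triggers growth
    max_step_displacement: float = 0.05   # nm per update
    update_interval: int = 10_000    # steps


@dataclass
class CellWall:
    grid: np.ndarray                 # (n_hoops, n_beads_per_hoop) system indices
    r_g: float
    hoop_spacing: float
    k_g: float = K_G
    k_p: float = K_P
    l_p: float = L_EXT
    l_g: np.ndarray = None           # (n_hoops - 1, N_b) per-spring relaxed length
    p_tg: float = P_TG
    k_w: float = K_W
    d_wm: float = D_WM

    @property
    def n_hoops(self) -> int:
        return self.grid.shape[0]

    @property
    def beads_per_hoop(self) -> int:
        return self.grid.shape[1]

    @property
    def bead_indices(self) -> np.ndarray:
        return self.grid.ravel()

    def hoop_radii(self, system: ParticleSystem) -> np.ndarray:
        p = system.positions[self.grid]
        return np.hypot(p[..., 1], p[..., 2]).mean(axis=1)

    def mean_radius(self, system: ParticleSystem) -> float:
        return float(system.radial(self.bead_indices).mean())


def build_wall(system: ParticleSystem, radius: float = 265.0,
               width: float = 160.0, spacing: float = 16.0,
               membrane_radius: float | None = None, **kw) -> CellWall:
    """Build the hoop grid; bead count per hoop from ``round(2πr/spacing)``."""
    if membrane_radius is not None and abs(radius - membrane_radius - D_WM) > 1e-6:
        raise ValueError("wall radius must sit 15 nm outside the membrane")
    n_hoops = int(round(width / spacing)) + 1     # includes the image hoop
    n_b = int(round(2 * np.pi * radius / spacing))
    phi = np.arange(n_b) * (2 * np.pi / n_b)
    grid = np.empty((n_hoops, n_b), dtype=np.int64)
    for h in range(n_hoops):
        pts = np.column_stack([
            np.full(n_b, h * spacing),
            radius * np.cos(phi), radius * np.sin(phi),
        ])
        grid[h] = system.add_beads(pts, WALL)
    wall = CellWall(grid=grid, r_g=radius, hoop_spacing=spacing, **kw)
    # turgor stretches glycan springs to the as-built bead spacing: use the
    # actual chord (≈ spacing up to bead-count rounding) so the built
    # cylinder is the turgor equilibrium
    chord = 2.0 * radius * np.sin(np.pi / n_b)
    l_g0 = initial_glycan_length(chord, wall.p_tg, radius, wall.k_g, wall.l_p)
    # glycan springs only on the n_hoops-1 unique hoops (last hoop = image)
    wall.l_g = np.full((n_hoops - 1, n_b), l_g0)
    return wall


# ---------------------------------------------------------------------------
# elastic forces

def _glycan_arrays(wall: CellWall):
    g = wall.grid[:-1]                       # unique hoops
    i = g.ravel()
    j = np.roll(g, -1, axis=1).ravel()
    return i, j, wall.l_g.ravel()


def _peptide_arrays(wall: CellWall):
    i = wall.grid[:-1].ravel()
    j = wall.grid[1:].ravel()
    return i, j


def wall_elastic_forces(system: ParticleSystem, wall: CellWall) -> None:
    gi, gj, lg = _glycan_arrays(wall)
    hookean_forces(system, gi, gj, wall.k_g, lg)
    pi, pj = _peptide_arrays(wall)
    hookean_forces(system, pi, pj, wall.k_p, wall.l_p)


def wall_elastic_energy(system: ParticleSystem, wall: CellWall) -> float:
    gi, gj, lg = _glycan_arrays(wall)
    pi, pj = _peptide_arrays(wall)
    return (hookean_energy(system, gi, gj, wall.k_g, lg)
            + hookean_energy(system, pi, pj, wall.k_p, wall.l_p))


# ---------------------------------------------------------------------------
# turgor pressure

def _wall_triangles(wall: CellWall):
    """Vertex index triples for the triangulated lateral surface.

    Each tetragon between adjacent hoops is split by one diagonal;
    vertex order is chosen so triangle normals point outward on the
    as-built cylinder (positive enclosed volume).
    """
    g = wall.grid
    a = g[:-1]
    b = np.roll(g[:-1], -1, axis=1)
    c = np.roll(g[1:], -1, axis=1)
    d = g[1:]
    t1 = np.stack([a.ravel(), b.ravel(), c.ravel()], axis=1)
    t2 = np.stack([a.ravel(), c.ravel(), d.ravel()], axis=1)
    return np.vstack([t1, t2])


def enclosed_volume(system: ParticleSystem, wall: CellWall) -> float:
    """Volume enclosed by the wall tube (divergence-theorem flux form).

    Uses the field F = (0, y, z)/2 whose divergence is 1: the volume is
    the flux of F through the triangulated lateral surface.  Because F
    has no axial component, the open tube ends contribute nothing and
    the result is exactly the tube volume; because F is invariant under
    axial translation, the periodic edge hoops see interior-like
    gradients (no spurious boundary force).
    """
    tri = _wall_triangles(wall)
    p = system.positions[tri]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    n = cross3(a, b)                          # 2x triangle vector area
    m = p.mean(axis=1)
    flux = n[:, 1] * m[:, 1] + n[:, 2] * m[:, 2]
    return float(0.25 * flux.sum())


def turgor_forces(system: ParticleSystem, wall: CellWall) -> None:
    """F_j = P_tg ∇_j V with the flux-form enclosed volume (outward)."""
    tri = _wall_triangles(wall)
    p = system.positions[tri]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    m = p.mean(axis=1)
    m[:, 0] = 0.0                             # field has no axial part
    n = cross3(a, b)
    n[:, 0] = 0.0                             # projected vector area term
    bxm = cross3(b, m)
    mxa = cross3(m, a)
    c = 0.25 * wall.p_tg
    g1 = c * (-bxm - mxa + n / 3.0)
    g2 = c * (bxm + n / 3.0)
    g3 = c * (mxa + n / 3.0)
    scatter_add(system.forces, tri[:, 0], g1)
    scatter_add(system.forces, tri[:, 1], g2)
    scatter_add(system.forces, tri[:, 2], g3)


def turgor_energy(system: ParticleSystem, wall: CellWall) -> float:
    """Potential -P_tg·V whose negative gradient is the turgor force."""
    return -wall.p_tg * enclosed_volume(system, wall)


# ---------------------------------------------------------------------------
# periodic edge tie

def apply_edge_tie(system: ParticleSystem, wall: CellWall) -> None:
    """Sum the forces on the two edge hoops and apply to both.

    Call after *all* forces (including random) are accumulated and
    before integration; keeps the edge hoops exact translational images.
    """
    e0 = wall.grid[0]
    e1 = wall.grid[-1]
    tot = system.forces[e0] + system.forces[e1]
    system.forces[e0] = tot
    system.forces[e1] = tot


# ---------------------------------------------------------------------------
# membrane coupling

def nearest_wall_map(system: ParticleSystem, wall: CellWall, membrane):
    """Index of the nearest wall bead (into the wall grid) per membrane bead."""
    tree = cKDTree(system.positions[wall.bead_indices])
    _, near = tree.query(system.positions[membrane.bead_indices])
    return near


def membrane_wall_gaps(system: ParticleSystem, wall: CellWall, membrane,
                       return_grads: bool = False, near=None):
    """Signed distance from each membrane bead to the local wall surface.

    The local surface is the tangent plane at the nearest wall bead,
    with normal from its hoop/axial neighbour differences, oriented
    outward.  Returns ``(g, nearest_wall_bead)`` and optionally the
    analytic gradient pieces used by the force routine.  ``near`` may be
    a cached nearest-bead map (refreshed with the neighbor lists).
    """
    mem = membrane.bead_indices
    if near is None:
        near = nearest_wall_map(system, wall, membrane)
    nh, nb = wall.n_hoops, wall.beads_per_hoop
    h = near // nb
    j = near % nb
    # neighbour indices (hoops 0..nh-1; axial neighbours clamp at the edges,
    # which are images of each other so the local plane stays well defined)
    jp = wall.grid[h, (j + 1) % nb]
    jm = wall.grid[h, (j - 1) % nb]
    hp = wall.grid[np.minimum(h + 1, nh - 1), j]
    hm = wall.grid[np.maximum(h - 1, 0), j]
    w_idx = wall.grid[h, j]
    u = system.positions[jp] - system.positions[jm]       # circumferential
    v = system.positions[hp] - system.positions[hm]       # axial
    nvec = cross3(u, v)
    # orient outward (away from the long axis)
    rad = system.positions[w_idx].copy()
    rad[:, 0] = 0.0
    sgn = np.sign(np.einsum("ij,ij->i", nvec, rad))
    sgn[sgn == 0] = 1.0
    nn = np.maximum(row_norm(nvec), MIN_DIST)
    nhat = sgn[:, None] * nvec / nn[:, None]
    wv = system.positions[w_idx] - system.positions[mem]
    g = np.einsum("ij,ij->i", wv, nhat)
    if not return_grads:
        return g, w_idx
    q = sgn[:, None] * (wv - g[:, None] * nhat) / nn[:, None]
    return g, w_idx, (mem, jp, jm, hp, hm, u, v, nhat, q)


def wall_membrane_forces(system: ParticleSystem, wall: CellWall,
                         membrane, near=None) -> None:
    """Squeeze force F_w = k_w Δd² restoring the 15-nm gap (exact gradient)."""
    _wall_membrane(system, wall, membrane, accumulate=True, near=near)


def wall_membrane_energy(system: ParticleSystem, wall: CellWall,
                         membrane, near=None) -> float:
    return _wall_membrane(system, wall, membrane, accumulate=False, near=near)


def _wall_membrane(system, wall, membrane, accumulate, near=None):
    g, w_idx, (mem, jp, jm, hp, hm, u, v, nhat, q) = membrane_wall_gaps(
        system, wall, membrane, return_grads=True, near=near)
    dd = g - wall.d_wm
    if not accumulate:
        return float(wall.k_w / 3.0 * np.sum(np.abs(dd) ** 3))
    coef = -wall.k_w * dd * np.abs(dd)        # -dE/dg
    vxq = cross3(v, q)
    qxu = cross3(q, u)
    scatter_add(system.forces, mem, -coef[:, None] * nhat)
    scatter_add(system.forces, w_idx, coef[:, None] * nhat)
    scatter_add(system.forces, jp, coef[:, None] * vxq)
    scatter_add(system.forces, jm, -coef[:, None] * vxq)
    scatter_add(system.forces, hp, coef[:, None] * qxu)
    scatter_add(system.forces, hm, -coef[:, None] * qxu)
    return 0.0


# ---------------------------------------------------------------------------
# growth

def wall_growth_step(system: ParticleSystem, wall: CellWall, membrane,
                     policy: WallGrowthPolicy, dt_elapsed: float,
                     near=None) -> int:
    """Move the wall inward where the membrane has pulled away.

    For every membrane bead whose wall gap exceeds ``d_w-m +
    gap_trigger``, the nearest wall bead is displaced inward (radially)
    by ``Δd_w = min(max_step_displacement, ν_w·Δt)`` and its two glycan
    springs' relaxed lengths are shortened by ``π Δd_w / N_b`` — growth
    only ever shortens.  Returns the number of wall beads moved.
    """
    g, w_idx = membrane_wall_gaps(system, wall, membrane, near=near)
    trig = g > wall.d_wm + policy.gap_trigger
    if not trig.any():
        return 0
    dd_w = min(policy.max_step_displacement, policy.nu_w * dt_elapsed)
    if dd_w <= 0:
        return 0
    moved = np.unique(w_idx[trig])
    nb = wall.beads_per_hoop
    shorten = np.pi * dd_w / nb
    first = wall.grid[0, 0]
    for wb in moved:
        flat = int(wb - first)
        h, j = flat // nb, flat % nb
        targets = [(h, j)]
        if h == 0:
            targets.append((wall.n_hoops - 1, j))     # edge image
        elif h == wall.n_hoops - 1:
            targets = [(0, j), (h, j)]
        for hh, jj in targets:
            bead = wall.grid[hh, jj]
            p = system.positions[bead]
            rho = max(np.hypot(p[1], p[2]), MIN_DIST)
            system.positions[bead, 1] -= dd_w * p[1] / rho
            system.positions[bead, 2] -= dd_w * p[2] / rho
        # the two glycan springs of the (unique-hoop) bead
        hu = 0 if h == wall.n_hoops - 1 else h
        wall.l_g[hu, j] = max(wall.l_g[hu, j] - shorten, L_G_FLOOR)
        wall.l_g[hu, (j - 1) % nb] = max(
            wall.l_g[hu, (j - 1) % nb] - shorten, L_G_FLOOR)
    return len(moved)
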