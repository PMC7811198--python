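"""Bead-sheet membrane on a cylinder.

The membrane is a single layer of beads that starts as a cylinder (long
axis = x).  Its mechanics combine

* short-range pairwise repulsion between *any* two membrane beads closer
  than the bead size ``d_mb`` (magnitude ``k_pair (d_mb - d)^2``),
* pairwise attraction between *paired* beads further apart than
  ``d_pair`` (magnitude ``k_pair (d - d_pair)^2``), which preserves sheet
  integrity,
* fluidity: the pair list is rebuilt periodically from bead proximity, so
  beads can exchange neighbours and flow along the sheet.  A candidate
  pair is dropped only when, projected onto the local tangent plane
  (looking outward along the local radial direction), it is crossed by
  more than one shorter pair — one degree of crossing is tolerated to
  avoid force jumps at rebuilds,
* bending stiffness: every four beads that share five pairs form a quad
  whose two diagonals are pulled together (toward coplanarity) with a
  force proportional to their separation, and
* a periodic boundary along the long axis: beads on one longitudinal
  edge interact with translated images of the opposite edge; internally
  this is realised as a minimum-image convention with period equal to
  the membrane width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import cross3, row_norm, ParticleSystem, MEMBRANE, scatter_add

log = logging.getLogger(__name__)

#: distance floor used to regularize coincident beads (nm)
MIN_DIST = 1e-3


@dataclass
class Membrane:
    bead_indices: np.ndarray
    width: float                  # axial period, nm
    radius0: float                # build radius, nm
    d_mb: float = 8.0             # bead size / repulsion onset, nm
    d_pair: float = 16.0          # attraction onset, nm
    k_pair: float = 1.0           # pN/nm^2
    k_mb: float = 8.0             # pN/nm
    rebuild_interval: int = 10_000
    # pair list (unordered, i < j), indices into the full system
    pair_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    pair_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    # quads: columns [a, c, b, d]; diagonals are (a, c) and (b, d)
    quads: np.ndarray = field(default_factory=lambda: np.empty((0, 4), dtype=np.int64))
    # repulsion proximity list (all membrane pairs within d_mb + skin)
    rep_i: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    rep_j: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def pair_set(self) -> set:
        return {(int(i), int(j)) for i, j in zip(self.pair_i, self.pair_j)}


# ---------------------------------------------------------------------------
# construction

def build_membrane_cylinder(
    system: ParticleSystem,
    radius: float = 250.0,
    width: float = 160.0,
    bead_spacing: float = 8.0,
    seed: int = 0,
    **params,
) -> Membrane:
    """Lay membrane beads on a cylinder and initialize pair list and quads.

    Beads sit on rings of equal axial spacing; each ring holds
    ``round(2*pi*radius/bead_spacing)`` beads and alternate rings are
    rotated by half an angular spacing, seeding a triangulable mesh.  The
    axial direction is periodic with period ``width`` (the last ring is
    the image of the first, so no duplicate ring is stored).
    """
    if radius <= bead_spacing or width <= 0 or bead_spacing <= 0:
        raise ValueError("membrane dimensions must be positive and radius > spacing")
    n_rows = int(round(width / bead_spacing))
    if abs(n_rows * bead_spacing - width) > 1e-9:
        raise ValueError("width must be a multiple of the axial bead spacing")
    n_ring = int(round(2 * np.pi * radius / bead_spacing))
    rows = np.arange(n_rows) * bead_spacing
    dphi = 2 * np.pi / n_ring
    pts = []
    for k, x in enumerate(rows):
        phi = np.arange(n_ring) * dphi + (k % 2) * dphi / 2
        pts.append(np.column_stack([
            np.full(n_ring, x), radius * np.cos(phi), radius * np.sin(phi)
        ]))
    pts = np.vstack(pts)
    idx = system.add_beads(pts, MEMBRANE)
    m = Membrane(bead_indices=idx, width=width, radius0=radius, **params)
    rebuild_pair_list(system, m)
    rebuild_repulsion_list(system, m)
    return m


# ---------------------------------------------------------------------------
# axial minimum image

def _wrap_dx(dx: np.ndarray, width: float) -> np.ndarray:
    """Wrap axial displacement into [-width/2, width/2)."""
    return dx - width * np.round(dx / width)


def _wrap_block(d: np.ndarray, width: float) -> np.ndarray:
    d = d.copy()
    d[:, 0] = _wrap_dx(d[:, 0], width)
    return d


def _pair_vectors(system: ParticleSystem, m: Membrane, i, j) -> np.ndarray:
    d = system.positions[j] - system.positions[i]
    d[:, 0] = _wrap_dx(d[:, 0], m.width)
    return d


def periodic_images(system: ParticleSystem, m: Membrane, cutoff: float | None = None):
    """Image coordinates for beads near the longitudinal edges.

    Returns ``(indices, image_positions)``: each listed bead has an image
    translated by ±width along the long axis, through which it interacts
    with the opposite edge.  Interior beads have no image.
    """
    if cutoff is None:
        cutoff = m.d_pair
    x = system.positions[m.bead_indices, 0] % m.width
    lo = x < cutoff
    hi = x > m.width - cutoff
    idx = m.bead_indices[lo | hi]
    shift = np.where(x[lo | hi] < cutoff, m.width, -m.width)
    img = system.positions[idx].copy()
    img[:, 0] += shift
    return idx, img


# ---------------------------------------------------------------------------
# pair list and quads

def _candidate_pairs(system: ParticleSystem, m: Membrane, cutoff: float):
    """All membrane bead pairs within ``cutoff`` (axial minimum image)."""
    pos = system.positions[m.bead_indices].copy()
    pos[:, 0] %= m.width
    pos[pos[:, 0] >= m.width, 0] = 0.0   # modulo can round up to the period
    # shift y/z positive and use a huge box in those directions so only x wraps
    big = 4 * (np.abs(pos[:, 1:]).max() + cutoff + 1.0)
    pos[:, 1:] += big / 2
    tree = cKDTree(pos, boxsize=[m.width, big, big])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return (np.empty(0, np.int64),) * 2
    i = m.bead_indices[pairs[:, 0]]
    j = m.bead_indices[pairs[:, 1]]
    swap = i > j
    i[swap], j[swap] = j[swap], i[swap]
    return i, j


def _segments_cross_2d(p1, p2, q1, q2) -> np.ndarray:
    """Vectorized proper-intersection test for 2D segments (p1,p2)-(q1,q2)."""
    def orient(a, b, c):
        return (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - \
               (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def rebuild_pair_list(system: ParticleSystem, m: Membrane) -> None:
    """Recompute the pair list from proximity, then prune crossed pairs.

    A pair is removed only if it is crossed — in the outward projection
    onto the local tangent plane — by more than one *shorter* pair.
    Quads are re-derived afterwards.
    """
    ci, cj = _candidate_pairs(system, m, m.d_pair)
    if len(ci) == 0:
        m.pair_i, m.pair_j = ci, cj
        m.quads = np.empty((0, 4), dtype=np.int64)
        return
    vec = _pair_vectors(system, m, ci, cj)
    length = row_norm(vec)
    mid = system.positions[ci] + 0.5 * vec

    # neighbouring pair segments: midpoints closer than d_pair can cross
    mp = mid.copy()
    mp[:, 0] %= m.width
    mp[mp[:, 0] >= m.width, 0] = 0.0
    big = 4 * (np.abs(mp[:, 1:]).max() + m.d_pair + 1.0)
    mp[:, 1:] += big / 2
    tree = cKDTree(mp, boxsize=[m.width, big, big])
    cand = tree.query_pairs(m.d_pair, output_type="ndarray")
    n_cross_shorter = np.zeros(len(ci), dtype=np.int64)
    if len(cand):
        a, b = cand[:, 0], cand[:, 1]
        share = (
            (ci[a] == ci[b]) | (ci[a] == cj[b]) |
            (cj[a] == ci[b]) | (cj[a] == cj[b])
        )
        a, b = a[~share], b[~share]
        if len(a):
            # local tangent frame at the joint midpoint: axial (x) and
            # circumferential unit vectors; project along the radial direction
            ctr = 0.5 * (mid[a] + mid[b])
            r = ctr.copy()
            r[:, 0] = 0.0
            rn = row_norm(r)[:, None]
            rn[rn < MIN_DIST] = 1.0
            rhat = r / rn
            that = cross3([1.0, 0.0, 0.0], rhat)  # circumferential

            def proj2d(pts, ref):
                d = pts - ref
                d[:, 0] = _wrap_dx(d[:, 0], m.width)
                return np.column_stack([d[:, 0], np.einsum("ij,ij->i", d, that)])

            p1 = proj2d(system.positions[ci[a]], ctr)
            p2 = proj2d(system.positions[ci[a]] + vec[a], ctr)
            q1 = proj2d(system.positions[ci[b]], ctr)
            q2 = proj2d(system.positions[ci[b]] + vec[b], ctr)
            crossed = _segments_cross_2d(p1, p2, q1, q2)
            a, b = a[crossed], b[crossed]
            shorter_b = length[b] < length[a]
            np.add.at(n_cross_shorter, a[shorter_b], 1)
            np.add.at(n_cross_shorter, b[~shorter_b], 1)

    keep = n_cross_shorter <= 1  # one degree of crossing allowed
    m.pair_i, m.pair_j = ci[keep], cj[keep]
    m.quads = _derive_quads(system, m)


def _derive_quads(system: ParticleSystem, m: Membrane) -> np.ndarray:
    """Four-bead sets sharing exactly five pairs, forming proper tetragons.

    Pattern: beads ``b`` and ``d`` are not paired but share two paired
    common neighbours ``a`` and ``c``; the perimeter a-b-c-d plus the
    diagonal a-c makes five pairs.  Diagonals of the quad are (a, c) and
    (b, d); only sets whose diagonals actually cross in the outward
    tangent-plane projection (a genuine tetragon, not a kite or sliver)
    are kept.
    """
    pairs = set(zip(m.pair_i.tolist(), m.pair_j.tolist()))
    adj: dict[int, set] = {}
    for i, j in pairs:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    quads = []
    seen = set()
    for a, c in pairs:
        common = sorted(adj[a] & adj[c])
        for u in range(len(common)):
            for v in range(u + 1, len(common)):
                b, d = common[u], common[v]
                if (min(b, d), max(b, d)) in pairs:
                    continue  # six pairs, not five
                key = frozenset((a, b, c, d))
                if key in seen:
                    continue
                seen.add(key)
                quads.append((a, c, b, d))
    q = np.array(quads, dtype=np.int64).reshape(-1, 4)
    if len(q) == 0:
        return q
    # keep only quads whose diagonals cross in the tangent projection
    pa = system.positions[q[:, 0]]
    pc = pa + _wrap_block(system.positions[q[:, 1]] - pa, m.width)
    pb = pa + _wrap_block(system.positions[q[:, 2]] - pa, m.width)
    pd = pa + _wrap_block(system.positions[q[:, 3]] - pa, m.width)
    ctr = 0.25 * (pa + pb + pc + pd)
    r = ctr.copy()
    r[:, 0] = 0.0
    rn = row_norm(r)[:, None]
    rn[rn < MIN_DIST] = 1.0
    rhat = r / rn
    that = cross3([1.0, 0.0, 0.0], rhat)

    def p2(pts):
        d_ = pts - ctr
        return np.column_stack([d_[:, 0], np.einsum("ij,ij->i", d_, that)])

    crossing = _segments_cross_2d(p2(pa), p2(pc), p2(pb), p2(pd))
    return q[crossing]


def rebuild_repulsion_list(system: ParticleSystem, m: Membrane, skin: float = 2.0):
    """Proximity list for the all-pairs short-range repulsion."""
    m.rep_i, m.rep_j = _candidate_pairs(system, m, m.d_mb + skin)


# ---------------------------------------------------------------------------
# forces and energies

def membrane_pair_forces(system: ParticleSystem, m: Membrane,
                         rng: np.random.Generator | None = None) -> None:
    """Accumulate pairwise repulsion/attraction (equal and opposite)."""
    # repulsion: any two membrane beads closer than d_mb
    for (ii, jj, mode) in ((m.rep_i, m.rep_j, "push"), (m.pair_i, m.pair_j, "pull")):
        if len(ii) == 0:
            continue
        vec = _pair_vectors(system, m, ii, jj)
        d = row_norm(vec)
        bad = d < MIN_DIST
        if bad.any():
            log.warning("coincident membrane beads regularized: %d", bad.sum())
            if rng is None:
                rng = np.random.default_rng(0)
            vec[bad] = rng.standard_normal((bad.sum(), 3))
            d[bad] = MIN_DIST
        u = vec / d[:, None]
        if mode == "push":
            act = d < m.d_mb
            mag = m.k_pair * (m.d_mb - d[act]) ** 2
        else:
            act = d > m.d_pair
            mag = m.k_pair * (d[act] - m.d_pair) ** 2
        if not act.any():
            continue
        sign = -1.0 if mode == "push" else 1.0
        f = (sign * mag)[:, None] * u[act]
        scatter_add(system.forces, ii[act], f)
        scatter_add(system.forces, jj[act], -f)


def membrane_pair_energy(system: ParticleSystem, m: Membrane) -> float:
    """Potential implied by the pair forces (cubic wells)."""
    e = 0.0
    for (ii, jj, mode) in ((m.rep_i, m.rep_j, "push"), (m.pair_i, m.pair_j, "pull")):
        if len(ii) == 0:
            continue
        d = row_norm(_pair_vectors(system, m, ii, jj))
        if mode == "push":
            over = np.clip(m.d_mb - d, 0.0, None)
        else:
            over = np.clip(d - m.d_pair, 0.0, None)
        e += (m.k_pair / 3.0) * np.sum(over ** 3)
    return float(e)


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    raise

@njit(cache=True)
def _quad_kernel(pos, quads, width, k_mb, forces, accumulate):
    """Diagonal-separation bending term, fused per quad.

    For quad [a, c, b, d] the signed separation ``s`` is the distance
    between the diagonals (a-c) and (b-d) along their common normal;
    the quad energy is ``k_mb s^2`` and forces are its exact negative
    gradient.  Returns the summed ``s^2`` (used for energy and for the
    stiffness calibration).
    """
    s2_total = 0.0
    for n in range(quads.shape[0]):
        a, c, b, d = quads[n, 0], quads[n, 1], quads[n, 2], quads[n, 3]
        ax, ay, az = pos[a, 0], pos[a, 1], pos[a, 2]
        # wrap along the periodic (x) axis relative to a
        cx = pos[c, 0] - width * round((pos[c, 0] - ax) / width)
        bx = pos[b, 0] - width * round((pos[b, 0] - ax) / width)
        dx_ = pos[d, 0] - width * round((pos[d, 0] - ax) / width)
        cy, cz = pos[c, 1], pos[c, 2]
        by, bz = pos[b, 1], pos[b, 2]
        dy, dz = pos[d, 1], pos[d, 2]
        ux, uy, uz = cx - ax, cy - ay, cz - az
        vx, vy, vz = dx_ - bx, dy - by, dz - bz
        wx = 0.5 * ((bx + dx_) - (ax + cx))
        wy = 0.5 * ((by + dy) - (ay + cy))
        wz = 0.5 * ((bz + dz) - (az + cz))
        nx = uy * vz - uz * vy
        ny = uz * vx - ux * vz
        nz = ux * vy - uy * vx
        nn = (nx * nx + ny * ny + nz * nz) ** 0.5
        if nn < 1e-9:
            continue  # degenerate (collinear) quad
        nhx, nhy, nhz = nx / nn, ny / nn, nz / nn
        s = wx * nhx + wy * nhy + wz * nhz
        s2_total += s * s
        if not accumulate:
            continue
        qx = (wx - s * nhx) / nn
        qy = (wy - s * nhy) / nn
        qz = (wz - s * nhz) / nn
        vqx = vy * qz - vz * qy
        vqy = vz * qx - vx * qz
        vqz = vx * qy - vy * qx
        qux = qy * uz - qz * uy
        quy = qz * ux - qx * uz
        quz = qx * uy - qy * ux
        coef = -2.0 * k_mb * s
        hx, hy, hz = 0.5 * nhx, 0.5 * nhy, 0.5 * nhz
        forces[a, 0] += coef * (-hx - vqx)
        forces[a, 1] += coef * (-hy - vqy)
        forces[a, 2] += coef * (-hz - vqz)
        forces[c, 0] += coef * (-hx + vqx)
        forces[c, 1] += coef * (-hy + vqy)
        forces[c, 2] += coef * (-hz + vqz)
        forces[b, 0] += coef * (hx - qux)
        forces[b, 1] += coef * (hy - quy)
        forces[b, 2] += coef * (hz - quz)
        forces[d, 0] += coef * (hx + qux)
        forces[d, 1] += coef * (hy + quy)
        forces[d, 2] += coef * (hz + quz)
    return s2_total


def _quad_s2(system: ParticleSystem, m: Membrane) -> float:
    """Summed squared diagonal separation over quads."""
    if len(m.quads) == 0:
        return 0.0
    return _quad_kernel(system.positions, m.quads, m.width, m.k_mb,
                        system.forces, False)


def membrane_bending_forces(system: ParticleSystem, m: Membrane) -> None:
    """Pull each quad's diagonals together: F = -grad(k_mb s^2) per quad.

    The per-bead force magnitude is about ``k_mb |s|`` for a symmetric
    quad; net force and net torque per quad vanish identically.
    """
    if len(m.quads) == 0:
        return
    _quad_kernel(system.positions, m.quads, m.width, m.k_mb,
                 system.forces, True)


def membrane_bending_energy(system: ParticleSystem, m: Membrane) -> float:
    return m.k_mb * _quad_s2(system, m)


def calibrate_kmb(system: ParticleSystem, m: Membrane,
                  k_m_exp_J: float = 2e-19) -> float:
    """Match the mesh bending energy of the built cylinder to theory.

    The simulated bending energy at unit stiffness is ``Σ s²`` over quads
    (bookkeeping ``E_sim = 2 Σ k_mb s²/2``); the continuum bending energy
    of a cylindrical membrane is ``E_exp = k_m_exp · π L / R``.  Returns
    the ``k_mb`` equating the two.
    """
    from .units import joules
    if len(m.quads) == 0:
        raise ValueError("no quads; cannot calibrate")
    s2 = _quad_s2(system, m)
    if s2 <= 1e-12:
        raise ValueError("mesh is planar (zero diagonal separation); "
                         "calibration impossible")
    e_exp = joules(k_m_exp_J) * np.pi * m.width / m.radius0
    return e_exp / s2
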