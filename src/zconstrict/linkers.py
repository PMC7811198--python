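"""FtsZ–membrane linkers: flexible, circumferentially constrained, rigid.

A linker tethers one filament anchor (a monomer bead in the sliding
model, a cube centre in the bending model) to one membrane bead.

* **flexible** — two identical springs (``k_lk`` = 20 pN/nm, relaxed
  length 8 nm each) joined at a free bead representing FtsA/ZipA; the
  joint carries no angular energy, so the linker rotates freely while
  holding the filament ≈16 nm from the membrane.
* **circumferential** — the flexible linker plus a restoring force
  ``k_c·d`` (``k_c`` = 20 pN/nm) on the membrane beads of *adjacent*
  linkers of the same filament whenever they separate by ``d`` along
  the cell's long axis, aligning the attachment row circumferentially.
* **rigid** — a single 16-nm spring (same ``k_lk``) plus a restoring
  force ``k_r·d`` (``k_r`` = 3 pN/nm) on its ends when they separate by
  ``d`` perpendicular to the radial direction, keeping the linker
  radial (and, with the division-plane constraint on the cubes,
  preventing filament rolling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import cross3, row_norm, ParticleSystem, LINKER, MEMBRANE, scatter_add
from .sliding import SlidingFilament, MIN_DIST
from .bending import CubeFilament

log = logging.getLogger(__name__)

FLEXIBLE, CIRCUMFERENTIAL, RIGID = "flexible", "circumferential", "rigid"

K_LK = 20.0     # pN/nm
L_LK = 8.0      # nm per spring (flexible); rigid uses a single 16-nm spring
K_C = 20.0      # pN/nm, circumferential alignment
K_R = 3.0       # pN/nm, radial alignment (rigid)


@dataclass
class LinkerSet:
    """All linkers of one filament, in minus-to-plus anchor order."""
    variant: str
    #: (L, k) anchor bead indices; the anchor point is their mean
    #: (k = 1 for bead filaments, 8 for cube filaments)
    anchor_beads: np.ndarray
    mem_beads: np.ndarray                     # (L,)
    joints: np.ndarray | None = None          # (L,) flexible/circumferential
    k_lk: float = K_LK
    l_lk: float = L_LK
    k_c: float = K_C
    k_r: float = K_R
    spacing: int = 4                          # monomers between anchors
    #: optional explicit adjacency (membrane-bead index pairs) for the
    #: circumferential constraint; defaults to consecutive linkers
    adj_i: np.ndarray | None = None
    adj_j: np.ndarray | None = None

    @property
    def n_linkers(self) -> int:
        return len(self.mem_beads)


def _anchor_array(filament, monomer_ids):
    if isinstance(filament, SlidingFilament):
        return np.asarray([[filament.beads[m]] for m in monomer_ids],
                          dtype=np.int64)
    rows = []
    for m in monomer_ids:
        rows.append(filament.cross_sections[m] + filament.cross_sections[m + 1])
    return np.asarray(rows, dtype=np.int64)


def attach_linkers(system: ParticleSystem, filament, membrane,
                   variant: str = FLEXIBLE, spacing: int = 4,
                   capture_radius: float = 24.0, **kw) -> LinkerSet:
    """Attach linkers every ``spacing`` monomers to nearest free membrane beads.

    Each linker claims a membrane bead not already claimed by this
    filament; anchors with no membrane bead inside ``capture_radius``
    are skipped (logged).  Flexible variants create the joint bead at
    the anchor–membrane midpoint.
    """
    n = (filament.n_beads if isinstance(filament, SlidingFilament)
         else filament.n_monomers)
    monomer_ids = list(range(0, n, spacing))
    anchors = _anchor_array(filament, monomer_ids)
    apos = system.positions[anchors].mean(axis=1)
    mem_idx = membrane.bead_indices
    tree = cKDTree(system.positions[mem_idx])
    claimed: set[int] = set()
    keep_rows, mem_rows = [], []
    for row, p in enumerate(apos):
        dists, cands = tree.query(p, k=8)
        found = None
        for d_, c_ in zip(np.atleast_1d(dists), np.atleast_1d(cands)):
            if d_ > capture_radius:
                break
            bead = int(mem_idx[c_])
            if bead not in claimed:
                found = bead
                break
        if found is None:
            log.warning("linker anchor %d skipped: no free membrane bead "
                        "within %.1f nm", row, capture_radius)
            continue
        claimed.add(found)
        keep_rows.append(row)
        mem_rows.append(found)
    anchors = anchors[keep_rows]
    mem_beads = np.asarray(mem_rows, dtype=np.int64)
    joints = None
    if variant in (FLEXIBLE, CIRCUMFERENTIAL):
        mid = 0.5 * (system.positions[anchors].mean(axis=1)
                     + system.positions[mem_beads])
        joints = system.add_beads(mid, LINKER)
    return LinkerSet(variant=variant, anchor_beads=anchors,
                     mem_beads=mem_beads, joints=joints,
                     spacing=spacing, **kw)


# ---------------------------------------------------------------------------
# forces / energies

def _center_spring(system, anchors, other, k, l0, accumulate):
    """Spring between the anchor-bead centroid and a single bead."""
    w = 1.0 / anchors.shape[1]
    pa = system.positions[anchors].mean(axis=1)
    pb = system.positions[other]
    vec = pb - pa
    d = np.maximum(row_norm(vec), MIN_DIST)
    if not accumulate:
        return float(0.5 * k * np.sum((d - l0) ** 2))
    u = vec / d[:, None]
    f = (k * (d - l0))[:, None] * u
    for col in range(anchors.shape[1]):
        scatter_add(system.forces, anchors[:, col], w * f)
    scatter_add(system.forces, other, -f)
    return 0.0


def _radial_alignment(system, lset: LinkerSet, accumulate):
    """Penalty ``½ k_r |s_perp|²`` on the rigid linker's off-radial span.

    ``s`` is the anchor-to-membrane-bead vector and the radial direction
    is taken from the long axis through the membrane bead; the gradient
    includes the dependence of that direction on the membrane bead.
    """
    anchors, mem = lset.anchor_beads, lset.mem_beads
    pa = system.positions[anchors].mean(axis=1)
    pm = system.positions[mem]
    s = pa - pm
    yz = pm.copy()
    yz[:, 0] = 0.0
    rho = np.maximum(row_norm(yz), MIN_DIST)
    rhat = yz / rho[:, None]
    a = np.einsum("ij,ij->i", s, rhat)
    if not accumulate:
        s2 = np.einsum("ij,ij->i", s, s)
        return float(0.5 * lset.k_r * np.sum(s2 - a * a))
    s_perp = s - a[:, None] * rhat
    # dE/danchor = k_r s_perp ; distribute over anchor beads
    ga = lset.k_r * s_perp
    w = 1.0 / anchors.shape[1]
    for col in range(anchors.shape[1]):
        scatter_add(system.forces, anchors[:, col], -w * ga)
    # dE/dmem = k_r[-s + a rhat - a (s_yz - a rhat)/rho]
    s_yz = s.copy()
    s_yz[:, 0] = 0.0
    gm = lset.k_r * (-s + a[:, None] * rhat
                     - (a / rho)[:, None] * (s_yz - a[:, None] * rhat))
    scatter_add(system.forces, mem, -gm)
    return 0.0


def _circumferential_alignment(system, lset: LinkerSet, accumulate):
    """Axial alignment of adjacent linkers' membrane beads: ``½ k_c dx²``."""
    if lset.adj_i is not None:
        i, j = lset.adj_i, lset.adj_j
    elif lset.n_linkers >= 2:
        i = lset.mem_beads[:-1]
        j = lset.mem_beads[1:]
    else:
        return 0.0
    if len(i) == 0:
        return 0.0
    dx = system.positions[j, 0] - system.positions[i, 0]
    if not accumulate:
        return float(0.5 * lset.k_c * np.sum(dx ** 2))
    fx = lset.k_c * dx
    n = system.n_beads
    system.forces[:, 0] += np.bincount(i, weights=fx, minlength=n)
    system.forces[:, 0] += np.bincount(j, weights=-fx, minlength=n)
    return 0.0


def linker_forces(system: ParticleSystem, lset: LinkerSet) -> None:
    _linker(system, lset, accumulate=True)


def linker_energy(system: ParticleSystem, lset: LinkerSet) -> float:
    return _linker(system, lset, accumulate=False)


def _linker(system, lset: LinkerSet, accumulate):
    if lset.n_linkers == 0:
        return 0.0
    e = 0.0
    if lset.variant == RIGID:
        e += _center_spring(system, lset.anchor_beads, lset.mem_beads,
                            lset.k_lk, 2 * lset.l_lk, accumulate)
        e += _radial_alignment(system, lset, accumulate)
    else:
        e += _center_spring(system, lset.anchor_beads, lset.joints,
                            lset.k_lk, lset.l_lk, accumulate)
        # joint-to-membrane spring (both plain beads)
        e += _center_spring(system, lset.joints[:, None], lset.mem_beads,
                            lset.k_lk, lset.l_lk, accumulate)
        if lset.variant == CIRCUMFERENTIAL:
            e += _circumferential_alignment(system, lset, accumulate)
    return e


# ---------------------------------------------------------------------------
# remodeling bookkeeping

def sync_after_remodel(system: ParticleSystem, lset: LinkerSet, filament,
                       membrane) -> None:
    """Drop linkers of removed monomers; attach at the plus end when due.

    A new plus-end monomer receives a linker once the monomer count
    since the last attachment reaches the spacing.
    """
    if isinstance(filament, SlidingFilament):
        alive = set(filament.beads)
        present = np.array([int(a[0]) in alive for a in lset.anchor_beads])
    else:
        alive = {id_ for cs_ in filament.cross_sections for id_ in cs_}
        present = np.array([all(int(b) in alive for b in row)
                            for row in lset.anchor_beads])
    if not present.all():
        if lset.joints is not None:
            for jb in lset.joints[~present]:
                system.mobile[jb] = False
                system.positions[jb] = 1e6
        lset.anchor_beads = lset.anchor_beads[present]
        lset.mem_beads = lset.mem_beads[present]
        if lset.joints is not None:
            lset.joints = lset.joints[present]

    # position (in monomers from the plus end) of the last anchored monomer
    if isinstance(filament, SlidingFilament):
        order = {b: k for k, b in enumerate(filament.beads)}
        last = max((order[int(a[0])] for a in lset.anchor_beads
                    if int(a[0]) in order), default=-1)
        n = filament.n_beads
    else:
        order = {tuple(cs_): k for k, cs_ in
                 enumerate(map(tuple, filament.cross_sections))}
        last = -1
        for row in lset.anchor_beads:
            key = tuple(int(b) for b in row[:4])
            for k, cs_ in enumerate(map(tuple, filament.cross_sections[:-1])):
                if cs_ == key:
                    last = max(last, k)
                    break
        n = filament.n_monomers
    if n - 1 - last >= lset.spacing:
        _attach_one(system, lset, filament, membrane, n - 1)


def _attach_one(system, lset: LinkerSet, filament, membrane, monomer_id):
    anchors = _anchor_array(filament, [monomer_id])
    p = system.positions[anchors[0]].mean(axis=0)
    mem_idx = membrane.bead_indices
    tree = cKDTree(system.positions[mem_idx])
    dists, cands = tree.query(p, k=8)
    claimed = set(int(b) for b in lset.mem_beads)
    for d_, c_ in zip(np.atleast_1d(dists), np.atleast_1d(cands)):
        bead = int(mem_idx[c_])
        if d_ <= 24.0 and bead not in claimed:
            lset.anchor_beads = np.vstack([lset.anchor_beads, anchors])
            lset.mem_beads = np.concatenate(
                [lset.mem_beads, np.array([bead], dtype=np.int64)])
            if lset.joints is not None:
                mid = 0.5 * (p + system.positions[bead])
                j = system.add_beads(mid[None, :], LINKER)
                lset.joints = np.concatenate([lset.joints, j])
            return
    log.warning("plus-end linker attachment skipped: no free membrane bead")


def merge_linker_sets(sets: list[LinkerSet]) -> LinkerSet | None:
    """Concatenate per-filament linker sets for batched force evaluation.

    Adjacency for the circumferential constraint is preserved within
    each filament and never spans filaments.
    """
    sets = [s for s in sets if s.n_linkers > 0]
    if not sets:
        return None
    first = sets[0]
    anchors = np.vstack([s.anchor_beads for s in sets])
    mem = np.concatenate([s.mem_beads for s in sets])
    joints = (np.concatenate([s.joints for s in sets])
              if first.joints is not None else None)
    adj_i, adj_j = [], []
    for s in sets:
        if s.n_linkers >= 2:
            adj_i.append(s.mem_beads[:-1])
            adj_j.append(s.mem_beads[1:])
    cat = (lambda lst: np.concatenate(lst) if lst
           else np.empty(0, dtype=np.int64))
    return LinkerSet(variant=first.variant, anchor_beads=anchors,
                     mem_beads=mem, joints=joints, k_lk=first.k_lk,
                     l_lk=first.l_lk, k_c=first.k_c, k_r=first.k_r,
                     spacing=first.spacing, adj_i=cat(adj_i), adj_j=cat(adj_j))
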