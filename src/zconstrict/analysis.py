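"""Post-processing metrics and the analytic calculators.

The analytic relations here tie the model's geometry and kinetics
together without any simulation:

* the constriction rate ``ν_radial`` is the mean reduction rate of the
  cell-wall bead radii between two times,
* the circumference-reduction rate is ``ν_cir = 2π ν_radial``,
* a closed ring of radius ``r`` built from filaments of mean length
  ``ℓ`` needs at least ``ceil(2π r / ℓ)`` filaments,
* the per-filament sliding rate is ``ν_cir / n_filaments``,
* the critical depolymerization rate above which rings break is the
  sliding rate expressed in subunits, ``r_c = 2π ν_radial / (n ℓ_z)``,
* a filament ring of diameter ``D`` bending in the same sense as the
  membrane and held at a gap ``g`` cannot constrict the membrane below
  ``D + 2g`` (24-nm minirings at a 16-nm gap stop at 56 nm).

Calculators return full precision; :func:`report` rounds to the
customary printed precision.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .system import ParticleSystem
from .sliding import SlidingFilament, L_Z
from .bending import CubeFilament


# ---------------------------------------------------------------------------
# analytic calculators

def constriction_rate(radii_t0: np.ndarray, radii_t: np.ndarray,
                      t0: float, t: float) -> float:
    """Mean reduction rate of wall bead radii between t0 and t (nm/s)."""
    if t <= t0:
        raise ValueError("t must exceed t0")
    n = len(radii_t0)
    return -(np.sum(radii_t) - np.sum(radii_t0)) / (n * (t - t0))


def circumference_reduction_rate(nu_radial: float) -> float:
    """ν_cir = 2π ν_radial (nm/s)."""
    return 2.0 * math.pi * nu_radial


def sliding_rate(nu_radial: float, n_filaments: int) -> float:
    """Per-filament sliding rate ν_cir / n (nm/s)."""
    return circumference_reduction_rate(nu_radial) / n_filaments


def critical_depolymerization_rate(nu_radial: float, n_filaments: int,
                                   l_z: float = L_Z) -> float:
    """r_c = 2π ν_radial / (n l_z) in beads/s.

    Depolymerizing faster than the ring can shrink opens gaps; rates
    above r_c break rings, rates below sustain them.
    """
    return 2.0 * math.pi * nu_radial / (n_filaments * l_z)


def min_filaments_per_ring(ring_radius: float, mean_length: float) -> int:
    """Minimum filament count to close a ring of the given radius."""
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    return math.ceil(2.0 * math.pi * ring_radius / mean_length)


def mean_filament_length(min_beads: int = 20, max_beads: int = 60,
                         l_z: float = L_Z) -> float:
    """Mean contour length of the uniform bead-count draw (nm).

    Bead counts 20–60 (88–264 nm) average 40 monomers ⇒ 176 nm.
    """
    return (min_beads + max_beads) / 2.0 * l_z


def same_sense_constriction_limit(ring_diameter: float,
                                  gap: float = 16.0) -> float:
    """Smallest membrane diameter reachable by same-sense bending (nm)."""
    if ring_diameter < 0 or gap < 0:
        raise ValueError("inputs must be non-negative")
    return ring_diameter + 2.0 * gap


def report(value: float, decimals: int = 1) -> float:
    """Round to the customary printed precision."""
    return round(value, decimals) if decimals > 0 else round(value)


# ---------------------------------------------------------------------------
# trajectory metrics

def constriction_rate_series(metrics, window: int = 2,
                             column: str = "wall_radius") -> np.ndarray:
    """Windowed constriction rate (nm/s) from a metrics table."""
    t = np.asarray(metrics["t"])
    r = np.asarray(metrics[column])
    if len(t) <= window:
        return np.empty(0)
    dt = t[window:] - t[:-window]
    dr = r[window:] - r[:-window]
    ok = dt > 0
    return np.where(ok, -dr / np.where(ok, dt, 1.0), np.nan)[ok]


def _ring_groups(filaments):
    groups: dict[int, list] = {}
    for f in filaments:
        groups.setdefault(f.ring_id, []).append(f)
    return groups


def ring_integrity(system: ParticleSystem, filaments,
                   overlap_threshold: float = 0.0,
                   bridge_tolerance: float = 0.0) -> dict[int, bool]:
    """Whether each ring's filaments cover the full circle.

    Bead positions are projected onto the ring's current best-fit plane
    about its centroid; a ring is intact iff the union of filament
    angular spans covers 2π, requiring pairwise end overlaps of at
    least ``overlap_threshold`` (arc length, nm).  ``bridge_tolerance``
    (arc length, nm) treats gaps narrower than the lateral-interaction
    reach as still mechanically connected — a ring transmits tension
    across a sub-bond-range gap even though bead coverage is
    interrupted.
    """
    out = {}
    for ring_id, fils in _ring_groups(filaments).items():
        beads = np.concatenate([_fil_points(system, f) for f in fils], axis=0)
        centroid = beads.mean(axis=0)
        # best-fit plane via SVD; normal = least-variance direction
        _, _, vt = np.linalg.svd(beads - centroid, full_matrices=False)
        e1, e2 = vt[0], vt[1]
        mean_r = np.linalg.norm(beads - centroid, axis=1).mean()
        pad = overlap_threshold / max(mean_r, 1e-9)   # arc -> angle
        bridge = 0.5 * bridge_tolerance / max(mean_r, 1e-9)
        spans = []
        for f in fils:
            p = _fil_points(system, f) - centroid
            ang = np.unwrap(np.arctan2(p @ e2, p @ e1))
            lo, hi = ang.min() - bridge, ang.max() + bridge - pad
            if hi <= lo:
                continue
            spans.append((lo, hi))
        out[ring_id] = _covers_circle(spans)
    return out


def _fil_points(system, f):
    if isinstance(f, SlidingFilament):
        return system.positions[np.asarray(f.beads, dtype=np.int64)]
    return f.cube_centers(system)


def _covers_circle(spans) -> bool:
    """Do the angular intervals cover the full circle (mod 2π)?"""
    if not spans:
        return False
    # normalize to [0, 2π) and split wrap-around intervals
    segs = []
    for lo, hi in spans:
        if hi - lo >= 2 * np.pi:
            return True
        lo_m = lo % (2 * np.pi)
        hi_m = lo_m + (hi - lo)
        if hi_m <= 2 * np.pi:
            segs.append((lo_m, hi_m))
        else:
            segs.append((lo_m, 2 * np.pi))
            segs.append((0.0, hi_m - 2 * np.pi))
    segs.sort()
    if segs[0][0] > 1e-12:
        return False
    reach = segs[0][1]
    for lo, hi in segs[1:]:
        if lo > reach + 1e-12:
            return False
        reach = max(reach, hi)
    return reach >= 2 * np.pi - 1e-12


def inter_ring_distance(system: ParticleSystem, filaments) -> float:
    """Mean nearest-bead distance between adjacent rings (bundling index)."""
    groups = _ring_groups(filaments)
    ids = sorted(groups)
    if len(ids) < 2:
        return float("nan")
    dists = []
    for a, b in zip(ids[:-1], ids[1:]):
        pa = np.concatenate([_fil_points(system, f) for f in groups[a]])
        pb = np.concatenate([_fil_points(system, f) for f in groups[b]])
        tree = cKDTree(pb)
        d, _ = tree.query(pa)
        dists.append(d.mean())
    return float(np.mean(dists))


def filament_membrane_distance(system: ParticleSystem, filaments,
                               membrane) -> dict:
    """Per-anchor minimal distance to the membrane beads; mean/sd summary."""
    if not filaments:
        return {"mean": float("nan"), "sd": float("nan"), "n": 0}
    pts = np.concatenate([_fil_points(system, f) for f in filaments])
    tree = cKDTree(system.positions[membrane.bead_indices])
    d, _ = tree.query(pts)
    return {"mean": float(d.mean()), "sd": float(d.std()), "n": len(d)}


def binormal_radial_alignment(system: ParticleSystem,
                              f: CubeFilament) -> float:
    """How radially the filament's bending plane normal points (0–1).

    The binormal of the cube-centre curve is ≈ axial for a filament
    bending within the division plane and turns radial when the
    filament rolls flat onto the membrane.  Returns the mean
    ``|binormal · r̂|`` over interior cubes.
    """
    c = f.cube_centers(system)
    if len(c) < 3:
        return float("nan")
    e = np.diff(c, axis=0)
    b = np.cross(e[:-1], e[1:])
    nb = np.linalg.norm(b, axis=1)
    ok = nb > 1e-9
    if not ok.any():
        return float("nan")
    b = b[ok] / nb[ok, None]
    mid = 0.5 * (c[:-2] + c[2:])[ok]
    r = mid.copy()
    r[:, 0] = 0.0
    rn = np.linalg.norm(r, axis=1, keepdims=True)
    rn[rn < 1e-9] = 1.0
    rhat = r / rn
    return float(np.mean(np.abs(np.einsum("ij,ij->i", b, rhat))))
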