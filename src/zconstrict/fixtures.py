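"""Deterministic miniature systems for tests and experiments.

These are small, fast-to-build assemblies — a short small-radius
membrane cylinder, a one-or-two-ring filament layout, a pair of
parallel chains at the lateral-potential minimum, a small wall —
generated programmatically so no fixture data ships with the package.
"""

from __future__ import annotations

import numpy as np

from . import membrane as mem_mod
from . import sliding as sl
from . import wall as wl
from .system import ParticleSystem

MINI_RADIUS = 60.0
MINI_WIDTH = 64.0


def make_fixture(kind: str, seed: int = 0):
    """Build a named miniature system; same seed ⇒ identical fixture.

    Kinds: ``mini_membrane``, ``mini_ring`` (membrane + one 3-filament
    ring), ``two_filaments`` (parallel 20-bead chains at lateral
    distance 2^(1/6)·ρ), ``mini_wall``.
    Returns ``(system, components)`` with a dict of named components.
    """
    rng = np.random.default_rng(seed)
    system = ParticleSystem()
    if kind == "mini_membrane":
        m = mem_mod.build_membrane_cylinder(
            system, MINI_RADIUS, MINI_WIDTH, 8.0, seed=seed)
        return system, {"membrane": m}
    if kind == "mini_ring":
        m = mem_mod.build_membrane_cylinder(
            system, MINI_RADIUS, MINI_WIDTH, 8.0, seed=seed)
        layout = sl.RingLayout(n_rings=1, ring_radius=MINI_RADIUS - 16.0,
                               min_beads=10, max_beads=20)
        fils = sl.init_ring_system(system, layout, rng, width=MINI_WIDTH)
        return system, {"membrane": m, "filaments": fils, "layout": layout}
    if kind == "two_filaments":
        gap = 2.0 ** (1.0 / 6.0) * sl.RHO
        n = 20
        z = np.arange(n) * sl.L_Z
        a = np.column_stack([np.zeros(n), np.zeros(n), z])
        b = np.column_stack([np.zeros(n), np.full(n, gap), z])
        ia = system.add_beads(a, 2)
        ib = system.add_beads(b, 2)
        fa = sl.SlidingFilament(beads=list(map(int, ia)), ring_id=0)
        fb = sl.SlidingFilament(beads=list(map(int, ib)), ring_id=0)
        return system, {"filaments": [fa, fb]}
    if kind == "mini_wall":
        w = wl.build_wall(system, radius=MINI_RADIUS + 15.0, width=MINI_WIDTH,
                          spacing=16.0)
        return system, {"wall": w}
    raise ValueError(f"unknown fixture kind {kind!r}")
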