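"""Flat particle arrays shared by every component.

The integrator advances a single :class:`ParticleSystem`; each structural
component (membrane, cell wall, filaments, linker joint beads) owns a slice
of its position/force arrays, identified by a component tag.  Force routines
accumulate into ``system.forces`` and never move beads themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# component tags (stored per bead; also used in trajectory output)
MEMBRANE = 0
WALL = 1
FTSZ = 2
LINKER = 3

TAG_NAMES = {MEMBRANE: "MEM", WALL: "WAL", FTSZ: "FTZ", LINKER: "LNK"}


@dataclass
class ParticleSystem:
    """Positions, forces and component tags for all beads.

    The cell's long axis is the x axis; the radial/circumferential
    directions live in the y–z plane.
    """

    positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.float64)
    )
    tags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    forces: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.float64)
    )
    #: per-bead mobility mask (False = frozen, excluded from integration)
    mobile: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def add_beads(self, positions: np.ndarray, tag: int) -> np.ndarray:
        """Append beads; returns their indices."""
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        start = self.n_beads
        n = positions.shape[0]
        self.positions = np.vstack([self.positions, positions])
        self.tags = np.concatenate([self.tags, np.full(n, tag, dtype=np.int8)])
        self.forces = np.vstack([self.forces, np.zeros((n, 3))])
        self.mobile = np.concatenate([self.mobile, np.ones(n, dtype=bool)])
        return np.arange(start, start + n)

    def zero_forces(self) -> None:
        self.forces[:] = 0.0

    def radial(self, idx=None) -> np.ndarray:
        """Distance from the long (x) axis."""
        p = self.positions if idx is None else self.positions[idx]
        return np.hypot(p[:, 1], p[:, 2])


def cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product; faster than np.cross for (n, 3) arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    out = np.empty(np.broadcast(a, b).shape)
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def row_norm(a: np.ndarray) -> np.ndarray:
    """Euclidean norm of each row of an (n, 3) array."""
    return np.sqrt(np.einsum("...i,...i->...", a, a))


def scatter_add(forces: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    """Accumulate per-interaction force contributions onto beads.

    ``np.bincount`` per component is markedly faster than ``np.add.at`` for
    the repeated-index patterns that spring lists produce.
    """
    if len(idx) == 0:
        return
    n = forces.shape[0]
    for k in range(3):
        forces[:, k] += np.bincount(idx, weights=contrib[:, k], minlength=n)
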