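"""Trajectory and metadata output.

Frames are written as multi-frame XYZ — the simplest format standard
molecular viewers (VMD etc.) load for a bonded-implicit point cloud —
with the per-bead component tag (MEM / WAL / FTZ / LNK) in the
atom-name column.  A minimal PDB writer is provided for viewers that
prefer it.  The run manifest is a JSON dump of the fully resolved
configuration.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

from .system import ParticleSystem, TAG_NAMES


def write_frame(system: ParticleSystem, path, fmt: str = "xyz",
                mode: str = "w", include_parked: bool = False) -> None:
    """Append (or write) one trajectory frame.

    Raises on non-finite coordinates, reporting the first bad bead.
    Parked (immobile, removed) beads are excluded by default.
    """
    sel = np.ones(system.n_beads, dtype=bool) if include_parked \
        else system.mobile.copy()
    pos = system.positions[sel]
    if len(pos) and not np.isfinite(pos).all():
        bad = int(np.where(~np.isfinite(pos).any(axis=1))[0][0])
        raise ValueError(f"non-finite coordinate at bead {bad}; frame not "
                         "written")
    tags = system.tags[sel]
    path = pathlib.Path(path)
    if fmt == "xyz":
        lines = [f"{len(pos)}", "zconstrict frame"]
        for (x, y, z), t in zip(pos, tags):
            lines.append(f"{TAG_NAMES[int(t)]} {x:.4f} {y:.4f} {z:.4f}")
        text = "\n".join(lines) + "\n"
        with open(path, mode) as fh:
            fh.write(text)
    elif fmt == "pdb":
        lines = []
        for n, ((x, y, z), t) in enumerate(zip(pos, tags), start=1):
            name = TAG_NAMES[int(t)]
            # coordinates in Å-sized columns; nm values are written as-is
            lines.append(
                f"ATOM  {n % 100000:5d} {name:<4s} {name:<3s} A"
                f"{n % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00")
        lines.append("END")
        with open(path, mode) as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown frame format {fmt!r}")


def read_xyz_frames(path):
    """Read all frames of a multi-frame XYZ file -> list of (tags, coords)."""
    frames = []
    lines = pathlib.Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        n = int(lines[k].strip())
        body = lines[k + 2:k + 2 + n]
        tags = [row.split()[0] for row in body]
        coords = np.array([[float(v) for v in row.split()[1:4]]
                           for row in body]) if n else np.empty((0, 3))
        frames.append((tags, coords))
        k += 2 + n
    return frames


def write_manifest(cfg, path) -> None:
    from . import __version__
    doc = {"package": "zconstrict", "version": __version__,
           "config": cfg.to_dict()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
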