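"""Recenter / rotate / assemble utilities and place-back export.

The place-back export writes a plain-text marker/transform file (one
line per kept particle: position, the tomogram-frame images of the three
local axes, and the curvature proxy) plus a cleaned STAR table with the
flagged particles removed. An optional ChimeraX-readable ``.cmm`` marker
file can be written alongside.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence
from xml.sax.saxutils import quoteattr

import numpy as np

from latticepick.cleaning import NeighborStats, classify_bad
from latticepick.core import Orientation, Particle, ParticleSet
from latticepick.io import write_star

__all__ = [
    "recenter",
    "yaxis_to_z",
    "export_placeback",
    "read_markers",
    "assemble",
]

# Frame change mapping local Y onto local Z: C @ z_hat == y_hat.
_Y_TO_Z = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])


def recenter(particles: ParticleSet, offset_local: Sequence[float]) -> ParticleSet:
    """Shift every particle by a local-frame offset; orientations unchanged."""
    offset_local = np.asarray(offset_local, dtype=float)
    out = particles.copy()
    for p in out:
        p.position = p.position + p.orientation.apply(offset_local)
    return out


def yaxis_to_z(particles: ParticleSet) -> ParticleSet:
    """Re-express orientations so the lattice axis is local Z instead of local Y.

    Each orientation is right-composed with the fixed frame change; after
    conversion the image of local Z equals the previous image of local Y.
    Positions are unchanged.
    """
    out = particles.copy()
    for p in out:
        p.orientation = Orientation.from_matrix(p.orientation.matrix @ _Y_TO_Z)
    return out


def export_placeback(
    particles: ParticleSet,
    stats: Sequence[NeighborStats],
    out_prefix: Path,
    min_neighbors: int = 3,
    max_tilt: float = 30.0,
    write_cmm: bool = False,
) -> tuple[Path, Path]:
    """Write the marker/transform file and the bad-particle-free STAR.

    Returns ``(marker_path, star_path)``. Columns of the marker file:
    ``x y z | xaxis(3) | yaxis(3) | zaxis(3) | curvature`` where the axis
    triplets are the tomogram-frame images of the local axes and
    ``curvature`` is the mean neighbor tilt in degrees (NaN when the
    particle has no neighbors).
    """
    if len(stats) != len(particles):
        raise ValueError(
            f"stats length {len(stats)} does not match particle count {len(particles)}"
        )
    flags = classify_bad(stats, min_neighbors, max_tilt)
    kept = [(p, s) for p, s, bad in zip(particles, stats, flags) if not bad]

    out_prefix = Path(out_prefix)
    marker_path = out_prefix.with_suffix(".markers.txt")
    star_path = out_prefix.with_suffix(".clean.star")

    lines = [
        "# x y z xaxis_x xaxis_y xaxis_z yaxis_x yaxis_y yaxis_z "
        "zaxis_x zaxis_y zaxis_z curvature_deg"
    ]
    for p, s in kept:
        m = p.orientation.matrix
        curv = float("nan") if s.curvature_proxy is None else s.curvature_proxy
        fields = list(p.position) + list(m[:, 0]) + list(m[:, 1]) + list(m[:, 2]) + [curv]
        lines.append(" ".join(f"{v:.6f}" for v in fields))
    marker_path.write_text("\n".join(lines) + "\n")

    write_star(
        ParticleSet([p.copy() for p, _ in kept], particles.tomo_name, particles.voxel_size),
        star_path,
    )

    if write_cmm:
        cmm_path = out_prefix.with_suffix(".cmm")
        cmm = ["<marker_set name=" + quoteattr(out_prefix.name) + ">"]
        for i, (p, _s) in enumerate(kept):
            cmm.append(
                f'<marker id="{i + 1}" x="{p.position[0]:.3f}" '
                f'y="{p.position[1]:.3f}" z="{p.position[2]:.3f}" radius="2"/>'
            )
        cmm.append("</marker_set>")
        cmm_path.write_text("\n".join(cmm) + "\n")
    return marker_path, star_path


def read_markers(path: Path) -> np.ndarray:
    """Parse a marker file back into an (N, 13) array of its columns."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(v) for v in line.split()])
    return np.asarray(rows).reshape(-1, 13)


def assemble(
    sets: Sequence[ParticleSet], d_min: Optional[float] = None
) -> ParticleSet:
    """Concatenate per-tomogram tables into one set.

    Tomogram names must be distinct; when ``d_min`` is given, duplicate
    positions within the same tomogram raise an error.
    """
    names = [s.tomo_name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate tomogram names in assembly: {sorted(names)}")
    merged: list[Particle] = []
    for s in sets:
        if d_min is not None:
            pos = s.positions()
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    if np.linalg.norm(pos[i] - pos[j]) < d_min:
                        raise ValueError(
                            f"particles {i} and {j} in tomogram {s.tomo_name!r} "
                            f"lie within d_min = {d_min}"
                        )
        for p in s:
            q = p.copy()
            if not q.tomo_name:
                q.tomo_name = s.tomo_name
            merged.append(q)
    return ParticleSet(merged, tomo_name="")
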