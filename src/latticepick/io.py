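"""File formats: STAR particle tables, MRC volumes, two-point seed files,
and expansion-parameter JSON.

Conventions:

* Volumes are exchanged as MRC mode 2 (32-bit float). In memory they are
  numpy arrays indexed ``[x, y, z]``; on disk the MRC sections run
  ``[z, y, x]`` as usual, so the array is transposed at the boundary.
* STAR tables follow the Relion-4 tomogram convention on write
  (coordinates in voxels, ZYZ Euler angles in degrees, the correlation
  score in ``rlnAutopickFigureOfMerit``). The reader tolerates extra
  columns.
* Seed files are plain text: six whitespace-separated numbers per line,
  ``x1 y1 z1 x2 y2 z2`` — two points whose midpoint is the particle
  center and whose direction defines the local Y axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import mrcfile
import numpy as np
import pandas as pd

from latticepick.core import ExpansionParams, Orientation, Particle, ParticleSet

__all__ = [
    "SeedPair",
    "seeds_from_pairs",
    "read_seed_pairs",
    "read_star",
    "write_star",
    "read_volume",
    "write_volume",
    "load_params",
    "save_params",
]

STAR_COLUMNS = [
    "rlnTomoName",
    "rlnCoordinateX",
    "rlnCoordinateY",
    "rlnCoordinateZ",
    "rlnAngleRot",
    "rlnAngleTilt",
    "rlnAnglePsi",
    "rlnAutopickFigureOfMerit",
]
_MANDATORY = ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]


@dataclass(frozen=True)
class SeedPair:
    """Two picked points defining one particle (center and Y axis)."""

    p1: np.ndarray
    p2: np.ndarray


def seeds_from_pairs(pairs: Sequence[SeedPair], tomo_name: str = "") -> ParticleSet:
    """Convert two-point picks to seed particles.

    The particle center is the midpoint; the orientation is the minimal
    rotation taking local +Y onto ``(p2 - p1) / |p2 - p1|`` (no spin
    about the axis — the restricted angular search absorbs the residual).
    """
    particles = []
    for i, pair in enumerate(pairs):
        p1 = np.asarray(pair.p1, dtype=float)
        p2 = np.asarray(pair.p2, dtype=float)
        axis = p2 - p1
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            raise ValueError(f"seed pair #{i} has coincident points {p1.tolist()}")
        u = axis / norm
        particles.append(
            Particle(
                position=(p1 + p2) / 2.0,
                orientation=_min_rotation_from_y(u),
                status="seed",
                tomo_name=tomo_name,
            )
        )
    return ParticleSet(particles, tomo_name)


def _min_rotation_from_y(u: np.ndarray) -> Orientation:
    y = np.array([0.0, 1.0, 0.0])
    c = float(np.clip(y @ u, -1.0, 1.0))
    axis = np.cross(y, u)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return Orientation.identity()
        # antiparallel: rotate 180 deg about X (deterministic choice)
        return Orientation.from_matrix(np.diag([1.0, -1.0, -1.0]))
    axis = axis / s
    angle = np.arctan2(s, c)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return Orientation.from_matrix(R)


def read_seed_pairs(path: Path) -> list[SeedPair]:
    pairs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = [float(v) for v in line.split()]
        if len(vals) != 6:
            raise ValueError(
                f"{path}:{ln}: expected 6 numbers (x1 y1 z1 x2 y2 z2), got {len(vals)}"
            )
        pairs.append(SeedPair(np.array(vals[:3]), np.array(vals[3:])))
    return pairs


# ---------------------------------------------------------------------------
# STAR


def write_star(particles: ParticleSet, path: Path) -> None:
    """Write a Relion-4-style particle table (deterministic formatting)."""
    lines = ["", "data_particles", "", "loop_"]
    lines += [f"_{name} #{i + 1}" for i, name in enumerate(STAR_COLUMNS)]
    for p in particles:
        cc = p.cc
        fom = 0.0 if cc is None or not (cc == cc) else cc
        o = p.orientation
        lines.append(
            f"{p.tomo_name or particles.tomo_name or 'tomo'}\t"
            f"{p.position[0]:.6f}\t{p.position[1]:.6f}\t{p.position[2]:.6f}\t"
            f"{o.rot:.6f}\t{o.tilt:.6f}\t{o.psi:.6f}\t{fom:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_star_block(text: str) -> pd.DataFrame:
    lines = [ln.strip() for ln in text.splitlines()]
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        if ln.startswith("data_"):
            columns, rows, in_loop = [], [], False
            continue
        if ln == "loop_":
            in_loop = True
            columns, rows = [], []
            continue
        if ln.startswith("_"):
            if in_loop:
                columns.append(ln.split()[0].lstrip("_"))
            continue
        if in_loop and columns:
            rows.append(ln.split())
    if not columns:
        raise ValueError("no loop_ data block found in STAR file")
    df = pd.DataFrame(rows, columns=columns[: len(rows[0])] if rows else columns)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def read_star(path: Path) -> ParticleSet:
    """Read a particle table; extra columns are tolerated and ignored."""
    text = Path(path).read_text()
    try:
        df = _parse_star_block(text)
    except ValueError:
        if "loop_" in text:
            raise
        return ParticleSet([])  # header-only empty table
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"STAR file {path} is missing mandatory column {col}")
    particles = []
    tomo_names = df["rlnTomoName"] if "rlnTomoName" in df.columns else None
    for i in range(len(df)):
        cc = (
            float(df["rlnAutopickFigureOfMerit"].iloc[i])
            if "rlnAutopickFigureOfMerit" in df.columns
            else None
        )
        particles.append(
            Particle(
                position=np.array(
                    [
                        df["rlnCoordinateX"].iloc[i],
                        df["rlnCoordinateY"].iloc[i],
                        df["rlnCoordinateZ"].iloc[i],
                    ],
                    dtype=float,
                ),
                orientation=Orientation(
                    float(df["rlnAngleRot"].iloc[i]) if "rlnAngleRot" in df.columns else 0.0,
                    float(df["rlnAngleTilt"].iloc[i]) if "rlnAngleTilt" in df.columns else 0.0,
                    float(df["rlnAnglePsi"].iloc[i]) if "rlnAnglePsi" in df.columns else 0.0,
                ),
                cc=cc,
                status="accepted",
                tomo_name=str(tomo_names.iloc[i]) if tomo_names is not None else "",
            )
        )
    tomo_name = particles[0].tomo_name if particles else ""
    return ParticleSet(particles, tomo_name)


# ---------------------------------------------------------------------------
# MRC


def read_volume(path: Path) -> tuple[np.ndarray, float]:
    """Read an MRC volume; returns ``(data[x, y, z], voxel_size_angstrom)``."""
    with mrcfile.open(str(path), permissive=True) as mrc:
        data = np.asarray(mrc.data, dtype=np.float32)
        voxel_size = float(mrc.voxel_size.x)
    return data.T.copy(), voxel_size


def write_volume(volume: np.ndarray, path: Path, voxel_size: float = 1.0) -> None:
    """Write a volume as MRC mode 2 (32-bit float)."""
    volume = np.asarray(volume)
    if volume.dtype != np.float32:
        volume = volume.astype(np.float32)
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(volume.T.copy())
        mrc.voxel_size = voxel_size
        # Fixed label instead of the library's timestamped one, so that
        # identical inputs produce byte-identical files.
        mrc.header.label.fill(b"")
        mrc.header.label[0] = b"latticepick volume"
        mrc.header.nlabl = 1


# ---------------------------------------------------------------------------
# Params JSON


def save_params(params: ExpansionParams, path: Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=1) + "\n")


def load_params(path: Path) -> ExpansionParams:
    return ExpansionParams.from_dict(json.loads(Path(path).read_text()))
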