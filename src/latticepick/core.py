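"""Geometry primitives shared by every picking stage.

Conventions
-----------
* Orientations are intrinsic ZYZ Euler angles ``(rot, tilt, psi)`` in
  degrees; the matrix form maps particle-local coordinates into tomogram
  coordinates (``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``, right-handed).
* Positions are continuous, 0-based voxel coordinates ``(x, y, z)`` with
  the origin at the volume corner.
* A particle's lattice-normal / symmetry axis is its local **Y** axis
  (two-point stalk convention); converting to a local-Z convention is an
  explicit post-processing step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "Particle",
    "ParticleSet",
    "TransitionList",
    "ExpansionParams",
    "orient_vector",
]

_STATUSES = ("seed", "candidate", "accepted", "rejected")


@dataclass(frozen=True)
class Orientation:
    """A rigid rotation as intrinsic ZYZ Euler angles in degrees."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix mapping local into tomogram coordinates."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "Orientation":
        """Build from a proper rotation matrix (det +1, orthonormal)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
        if abs(np.linalg.det(matrix) - 1.0) > 1e-6:
            raise ValueError("matrix is not a proper rotation (det != +1)")
        import warnings

        with warnings.catch_warnings():
            # At tilt = 0/180 the ZYZ decomposition is degenerate; scipy's
            # convention (third angle zero) is a fine deterministic choice.
            warnings.filterwarnings("ignore", message="Gimbal lock")
            rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
        return cls(float(rot), float(tilt), float(psi))

    @classmethod
    def from_rotvec(cls, rotvec_deg: Sequence[float]) -> "Orientation":
        """Build from an axis-angle vector whose norm is the angle in degrees."""
        return cls.from_matrix(
            Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True).as_matrix()
        )

    def apply(self, v: Sequence[float]) -> np.ndarray:
        """Rotate a local-frame vector into the tomogram frame."""
        return self.matrix @ np.asarray(v, dtype=float)

    def compose(self, other: "Orientation") -> "Orientation":
        """Intrinsic composition: ``self`` followed by ``other`` in the rotated frame."""
        return Orientation.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "Orientation":
        return Orientation.from_matrix(self.matrix.T)

    def angle_to(self, other: "Orientation") -> float:
        """Axis-angle distance to another orientation, in degrees."""
        rel = self.matrix.T @ other.matrix
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(rel).as_rotvec()))
        )


def orient_vector(o: Orientation, v: Sequence[float]) -> np.ndarray:
    """Apply the ZYZ rotation of ``o`` to vector ``v`` (local -> tomogram)."""
    return o.apply(v)


@dataclass
class Particle:
    """One picked (or proposed) particle.

    ``cc`` is the correlation score of the last alignment; seeds carry
    ``None`` until first aligned. ``iteration_added`` is the expansion
    iteration at which the particle entered the final set (0 for seeds).
    """

    position: np.ndarray
    orientation: Orientation = field(default_factory=Orientation.identity)
    cc: Optional[float] = None
    status: str = "seed"
    iteration_added: int = 0
    tomo_name: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.status not in _STATUSES:
            raise ValueError(
                f"status must be one of {_STATUSES}, got {self.status!r}"
            )
        if self.cc is not None and not np.isnan(self.cc):
            if not -1.0 - 1e-9 <= self.cc <= 1.0 + 1e-9:
                raise ValueError(f"cc must lie in [-1, 1], got {self.cc}")
        if self.iteration_added < 0:
            raise ValueError("iteration_added must be >= 0")

    def copy(self, **changes) -> "Particle":
        p = dataclasses.replace(self, **changes)
        p.position = p.position.copy()
        return p


class ParticleSet:
    """Ordered collection of particles from one tomogram."""

    def __init__(
        self,
        particles: Optional[Sequence[Particle]] = None,
        tomo_name: str = "",
        voxel_size: Optional[float] = None,
    ):
        self.particles: list[Particle] = list(particles) if particles else []
        self.tomo_name = tomo_name
        self.voxel_size = voxel_size

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self) -> Iterator[Particle]:
        return iter(self.particles)

    def __getitem__(self, idx):
        return self.particles[idx]

    def add(self, particle: Particle) -> None:
        self.particles.append(particle)

    def positions(self) -> np.ndarray:
        """(N, 3) array of particle positions (x, y, z)."""
        if not self.particles:
            return np.zeros((0, 3))
        return np.stack([p.position for p in self.particles])

    def min_pair_distance(self) -> float:
        """Smallest pairwise distance among seed/accepted particles; inf if < 2."""
        pos = np.stack(
            [p.position for p in self.particles if p.status in ("seed", "accepted")]
        ) if any(p.status in ("seed", "accepted") for p in self.particles) else np.zeros((0, 3))
        if len(pos) < 2:
            return float("inf")
        from scipy.spatial.distance import pdist

        return float(pdist(pos).min())

    def copy(self) -> "ParticleSet":
        return ParticleSet(
            [p.copy() for p in self.particles], self.tomo_name, self.voxel_size
        )


@dataclass
class TransitionList:
    """Lattice-topology prior: local-frame displacements to expected neighbors."""

    transitions: np.ndarray

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float).reshape(-1, 3)
        if len(self.transitions) == 0:
            raise ValueError("transition list must be non-empty")
        norms = np.linalg.norm(self.transitions, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("every transition must have nonzero length")

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size == 1:
        return (float(arr[0]),) * 3
    if arr.size == 3:
        return tuple(float(x) for x in arr)
    raise ValueError(f"expected a scalar or 3-vector, got {value!r}")


@dataclass
class ExpansionParams:
    """Control block for one expansion run (JSON-serializable).

    ``angular_ranges`` / ``angular_steps`` are half-ranges and steps in
    degrees for the three angular offset axes; ``translational_range`` /
    ``translational_step`` are in voxels. ``spacing`` is the expected
    neighbor distance; ``d_min`` (default ``0.5 * spacing``) is the
    deduplication distance below which two picks count as one site.
    """

    transition_list: TransitionList
    spacing: float
    cc_threshold: float
    box_size: int
    angular_ranges: tuple[float, float, float] = (8.0, 8.0, 8.0)
    angular_steps: tuple[float, float, float] = (4.0, 4.0, 4.0)
    translational_range: float = 2.0
    translational_step: float = 1.0
    max_iterations: int = 20
    d_min: Optional[float] = None

    def __post_init__(self) -> None:
        if not isinstance(self.transition_list, TransitionList):
            self.transition_list = TransitionList(self.transition_list)
        self.angular_ranges = _as_triple(self.angular_ranges)
        self.angular_steps = _as_triple(self.angular_steps)
        for rng, step in zip(self.angular_ranges, self.angular_steps):
            if rng < 0:
                raise ValueError("angular half-ranges must be >= 0")
            if rng > 0 and step <= 0:
                raise ValueError("angular step must be > 0 where the range is > 0")
        if self.translational_range > 0 and self.translational_step <= 0:
            raise ValueError("translational step must be > 0 where the range is > 0")
        if not -1.0 < self.cc_threshold <= 1.0:
            raise ValueError("cc_threshold must lie in (-1, 1]")
        if self.box_size < 2:
            raise ValueError("box_size must be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.d_min is None:
            self.d_min = 0.5 * self.spacing
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")

    def to_dict(self) -> dict:
        return {
            "transition_list": self.transition_list.transitions.tolist(),
            "spacing": self.spacing,
            "cc_threshold": self.cc_threshold,
            "box_size": self.box_size,
            "angular_ranges": list(self.angular_ranges),
            "angular_steps": list(self.angular_steps),
            "translational_range": self.translational_range,
            "translational_step": self.translational_step,
            "max_iterations": self.max_iterations,
            "d_min": self.d_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExpansionParams":
        return cls(
            transition_list=TransitionList(np.asarray(d["transition_list"])),
            spacing=float(d["spacing"]),
            cc_threshold=float(d["cc_threshold"]),
            box_size=int(d["box_size"]),
            angular_ranges=_as_triple(d.get("angular_ranges", 8.0)),
            angular_steps=_as_triple(d.get("angular_steps", 4.0)),
            translational_range=float(d.get("translational_range", 2.0)),
            translational_step=float(d.get("translational_step", 1.0)),
            max_iterations=int(d.get("max_iterations", 20)),
            d_min=None if d.get("d_min") is None else float(d["d_min"]),
        )
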