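"""Geometry-based particle cleaning.

Each particle is scored by its neighbor count within a radius and by the
mean angle between its lattice-normal axis (local Y mapped into the
tomogram frame) and those of its neighbors — a proxy for local surface
curvature. Particles with too few neighbors or too large a mean tilt
are flagged as bad.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from latticepick.core import ParticleSet

__all__ = ["NeighborStats", "neighbor_stats", "classify_bad"]

_LOCAL_Y = np.array([0.0, 1.0, 0.0])


@dataclass
class NeighborStats:
    """Per-particle neighborhood summary.

    ``mean_tilt`` is ``None`` when the particle has no neighbor within
    the radius; ``curvature_proxy`` aliases it for export/coloring.
    """

    neighbor_count: int
    mean_tilt: Optional[float]

    @property
    def curvature_proxy(self) -> Optional[float]:
        return self.mean_tilt


def neighbor_stats(
    particles: ParticleSet, radius: float, fold_axes: bool = False
) -> list[NeighborStats]:
    """Neighbor count and mean inter-axis angle for every particle.

    Neighbors are particles within Euclidean ``radius`` (self excluded).
    The tilt between two particles is the angle between their tomogram-
    frame local-Y axes, in [0, 180] degrees; with ``fold_axes`` the axes
    are treated as undirected and the angle folded into [0, 90].
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = len(particles)
    if n == 0:
        return []
    positions = particles.positions()
    axes = np.stack([p.orientation.apply(_LOCAL_Y) for p in particles])
    tree = cKDTree(positions)
    stats: list[NeighborStats] = []
    for i in range(n):
        idx = [j for j in tree.query_ball_point(positions[i], radius) if j != i]
        if not idx:
            stats.append(NeighborStats(0, None))
            continue
        cosines = np.clip(axes[idx] @ axes[i], -1.0, 1.0)
        angles = np.degrees(np.arccos(cosines))
        if fold_axes:
            angles = np.minimum(angles, 180.0 - angles)
        stats.append(NeighborStats(len(idx), float(angles.mean())))
    return stats


def classify_bad(
    stats: Sequence[NeighborStats], min_neighbors: int, max_tilt: float
) -> np.ndarray:
    """Boolean flag per particle: bad when under-connected or over-tilted.

    ``bad == (neighbor_count < min_neighbors) or (mean_tilt > max_tilt)``;
    particles without neighbors fail only the count test.
    """
    flags = np.zeros(len(stats), dtype=bool)
    for i, s in enumerate(stats):
        if s.neighbor_count < min_neighbors:
            flags[i] = True
        elif s.mean_tilt is not None and s.mean_tilt > max_tilt:
            flags[i] = True
    return flags
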