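"""Label-volume generation and clustering-based coordinate retrieval.

These are the deterministic halves of segmentation-driven picking:
turning particle coordinates into binary cube-label volumes (training
targets for an external voxel classifier) and turning segmentation /
probability maps back into particle coordinates via single-linkage
clustering of lit voxels.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import label as cc_label
from scipy.spatial import cKDTree

__all__ = ["labels_from_coords", "coords_from_labels", "default_cube_side"]

# Above this many lit voxels, single-linkage falls back to a KD-tree
# union-find over <=cutoff pairs: the flat clusters of single linkage cut
# at the cutoff are exactly the connected components of that pair graph,
# so the result is identical while memory stays bounded.
_LINKAGE_MAX_VOXELS = 20000


def default_cube_side(spacing: float) -> int:
    """Default label-cube side: odd, about a quarter of the lattice spacing."""
    side = int(round(0.25 * spacing))
    if side % 2 == 0:
        side += 1
    return max(3, side)


def labels_from_coords(
    coords: Sequence[Sequence[float]], cube_side: int, shape: Sequence[int]
) -> np.ndarray:
    """Binary volume with an axis-aligned cube of 1s centered on each coordinate.

    Cubes are centered at the rounded coordinates, unioned over particles
    and clipped at the volume borders.
    """
    if cube_side < 1 or cube_side % 2 == 0:
        raise ValueError("cube_side must be odd and >= 1")
    shape = tuple(int(s) for s in shape)
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    bad = [
        i
        for i, c in enumerate(coords)
        if np.any(c < 0) or np.any(c > np.asarray(shape) - 1)
    ]
    if bad:
        raise ValueError(
            "coordinates outside the volume: "
            + ", ".join(f"#{i} at {coords[i].tolist()}" for i in bad)
        )
    vol = np.zeros(shape, dtype=np.uint8)
    half = cube_side // 2
    for c in np.rint(coords).astype(int):
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return vol


def _union_find_clusters(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Cluster ids from union-find over all point pairs within ``cutoff``."""
    n = len(points)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(r=cutoff, output_type="ndarray"):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def coords_from_labels(
    labels: np.ndarray,
    binarize_at: float = 0.5,
    linkage_cutoff: float = 3.0,
    min_voxels: int = 10,
) -> np.ndarray:
    """Cluster lit voxels and return one centroid per surviving cluster.

    Voxels with value >= ``binarize_at`` are grouped by single-linkage
    agglomerative clustering with distance cutoff ``linkage_cutoff``;
    clusters smaller than ``min_voxels`` are discarded. Accepts binary
    label volumes and probability maps alike. An all-zero map yields an
    empty (0, 3) array.
    """
    if linkage_cutoff <= 0:
        raise ValueError("linkage_cutoff must be > 0")
    lit = np.argwhere(np.asarray(labels) >= binarize_at).astype(float)
    if len(lit) == 0:
        return np.zeros((0, 3))
    if len(lit) == 1:
        ids = np.zeros(1, dtype=int)
    elif len(lit) <= _LINKAGE_MAX_VOXELS:
        z = linkage(lit, method="single")
        ids = fcluster(z, t=linkage_cutoff, criterion="distance")
    else:
        ids = _union_find_clusters(lit, linkage_cutoff)
    centroids = []
    for cid in np.unique(ids):
        members = lit[ids == cid]
        if len(members) < min_voxels:
            continue
        centroids.append(members.mean(axis=0))
    if not centroids:
        return np.zeros((0, 3))
    order = np.lexsort(
        tuple(np.asarray(centroids)[:, k] for k in (2, 1, 0))
    )  # deterministic output order
    return np.asarray(centroids)[order]


def connected_component_count(labels: np.ndarray, binarize_at: float = 0.5) -> int:
    """Number of 26-connected components among lit voxels (test oracle)."""
    binary = np.asarray(labels) >= binarize_at
    _, n = cc_label(binary, structure=np.ones((3, 3, 3), dtype=int))
    return int(n)
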