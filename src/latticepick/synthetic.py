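"""Synthetic lattices, rendered tomograms, and the two-patch worked-example fixture.

Everything downstream is testable against these generators: they provide
ground-truth site positions and frames (:class:`LatticeTruth`), a small
asymmetric template whose orientation is recoverable, and deterministic
noise. Volumes are numpy arrays indexed ``[x, y, z]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from latticepick.core import ExpansionParams, Orientation, Particle, TransitionList

__all__ = [
    "LatticeTruth",
    "Fig3Fixture",
    "default_template",
    "embed_template",
    "spherical_mask",
    "hexagonal_transitions",
    "filament_transitions",
    "planar_frame",
    "make_planar_lattice",
    "make_spherical_lattice",
    "make_filament_lattice",
    "make_fig3_fixture",
    "render_tomogram",
]

# Axial-coordinate offsets of the six hexagonal neighbors.
HEX_NEIGHBOR_OFFSETS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


@dataclass
class LatticeTruth:
    """Ground-truth lattice sites: positions, local frames, patch labels."""

    positions: np.ndarray  # (N, 3) voxel coordinates
    frames: list[Orientation]
    patch_ids: np.ndarray  # (N,) int
    spacing: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.patch_ids = np.asarray(self.patch_ids, dtype=int).reshape(-1)
        if not (len(self.positions) == len(self.frames) == len(self.patch_ids)):
            raise ValueError("positions, frames and patch_ids must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def nearest_neighbor_distances(self) -> np.ndarray:
        """Distance from each site to its nearest same-patch neighbor."""
        out = np.full(len(self), np.inf)
        for pid in np.unique(self.patch_ids):
            idx = np.nonzero(self.patch_ids == pid)[0]
            if len(idx) < 2:
                continue
            tree = cKDTree(self.positions[idx])
            d, _ = tree.query(self.positions[idx], k=2)
            out[idx] = d[:, 1]
        return out


def default_template(side: int = 11) -> np.ndarray:
    """Small asymmetric density whose pose is sharply recoverable.

    A soft central anchor, a three-fold ring of sharp unequal blobs in
    the local X-Z plane, and a blob along local +Y together break every
    rotational symmetry with strong leverage: rotating the template a
    few degrees displaces the sharp off-center blobs by a substantial
    fraction of their width, so the correlation peak is well curved in
    all three angles as well as in translation.
    """
    c = (side - 1) / 2.0
    ax = np.arange(side) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    # Ring blobs at scrambled angles AND radii with most of the energy:
    # no rotation maps the set close to itself, so every wrong spin
    # (including 60/120-degree lattice branches) costs a large
    # correlation drop (worst wrong-spin autocorrelation ~0.82).
    blobs = [
        ((0.0, 0.0, 0.0), 1.5, 0.35),
        ((2.4, 0.0, 0.0), 0.85, 1.2),
        (
            (1.6 * np.cos(np.radians(110.0)), 0.0, 1.6 * np.sin(np.radians(110.0))),
            0.8,
            0.95,
        ),
        (
            (3.0 * np.cos(np.radians(235.0)), 0.0, 3.0 * np.sin(np.radians(235.0))),
            0.9,
            0.6,
        ),
        ((0.0, 2.4, 0.0), 0.85, 0.75),
    ]
    vol = np.zeros((side, side, side))
    for (bx, by, bz), sigma, amp in blobs:
        r2 = (x - bx) ** 2 + (y - by) ** 2 + (z - bz) ** 2
        vol += amp * np.exp(-r2 / (2.0 * sigma**2))
    return vol.astype(np.float32)


def embed_template(template: np.ndarray, box_size: int) -> np.ndarray:
    """Center a (smaller) template volume inside a cubic box of ``box_size``."""
    side = template.shape[0]
    if template.shape != (side, side, side):
        raise ValueError("template must be cubic")
    if side > box_size:
        raise ValueError(f"template side {side} exceeds box_size {box_size}")
    out = np.zeros((box_size, box_size, box_size), dtype=template.dtype)
    # Align the template center voxel with the box center voxel box//2.
    lo = box_size // 2 - side // 2
    out[lo : lo + side, lo : lo + side, lo : lo + side] = template
    return out


def make_lattice_reference(
    template: np.ndarray, box_size: int, spacing: float
) -> np.ndarray:
    """Reference with the template at the box center plus its six ideal
    hexagonal neighbors, all in the particle local frame.

    Real lattice references (averaged subtomograms) contain the
    surrounding subunits; modelling them makes neighbor density signal
    rather than an unmodelled distortion of the correlation, and the
    neighbor ring gives strong leverage on the in-plane spin.
    """
    side = template.shape[0]
    if template.shape != (side, side, side):
        raise ValueError("template must be cubic")
    out = np.zeros((box_size, box_size, box_size), dtype=np.float64)
    c_box = box_size // 2
    c_t = (side - 1) / 2.0
    ax = np.arange(box_size, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()])
    centers = [np.array([c_box, c_box, c_box], dtype=float)]
    ang = np.radians(60.0 * np.arange(6))
    for a in ang:
        centers.append(
            centers[0] + spacing * np.array([np.cos(a), 0.0, np.sin(a)])
        )
    for ctr in centers:
        local = pts - ctr[:, None] + c_t
        vals = map_coordinates(
            template.astype(np.float64), local, order=1, mode="constant", cval=0.0
        )
        out += vals.reshape(out.shape)
    return out.astype(np.float32)


def spherical_mask(box_size: int, radius: float) -> np.ndarray:
    """Soft-edged spherical mask centered on voxel ``box_size // 2``."""
    c = box_size // 2
    ax = np.arange(box_size) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    return np.clip(radius + 1.0 - r, 0.0, 1.0).astype(np.float32)


def planar_frame(spin_deg: float = 0.0) -> Orientation:
    """Frame with local Y along tomogram +Z and local X/Z in the XY plane.

    ``spin_deg`` rotates the in-plane axes about the lattice normal.
    """
    base = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
    s = np.radians(spin_deg)
    spin = np.array(  # about local Y, applied first
        [[np.cos(s), 0.0, np.sin(s)], [0.0, 1.0, 0.0], [-np.sin(s), 0.0, np.cos(s)]]
    )
    return Orientation.from_matrix(base @ spin)


def hexagonal_transitions(spacing: float) -> TransitionList:
    """Six in-plane local-frame displacements of length ``spacing`` at 60 deg steps.

    In-plane means the local X-Z plane, perpendicular to the local-Y
    lattice normal.
    """
    ang = np.radians(60.0 * np.arange(6))
    return TransitionList(
        spacing * np.stack([np.cos(ang), np.zeros(6), np.sin(ang)], axis=1)
    )


def filament_transitions(spacing: float) -> TransitionList:
    """In-chain transitions for a 1D repeat: +/- spacing along local X."""
    return TransitionList(np.array([[spacing, 0.0, 0.0], [-spacing, 0.0, 0.0]]))


def hex_axial_sites(hex_radius: int) -> list[tuple[int, int]]:
    """Axial coordinates (q, r) with max(|q|, |r|, |q+r|) <= hex_radius."""
    sites = []
    for q in range(-hex_radius, hex_radius + 1):
        for r in range(-hex_radius, hex_radius + 1):
            if max(abs(q), abs(r), abs(q + r)) <= hex_radius:
                sites.append((q, r))
    return sites


def axial_to_cartesian(q: float, r: float, spacing: float) -> np.ndarray:
    return spacing * np.array([q + r / 2.0, r * np.sqrt(3.0) / 2.0, 0.0])


def make_planar_lattice(
    hex_radius: int,
    spacing: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    exclude: Sequence[tuple[int, int]] = (),
    patch_id: int = 0,
) -> LatticeTruth:
    """Flat hexagonal patch in the tomogram XY plane, all frames identical."""
    center = np.asarray(center, dtype=float)
    frame = planar_frame()
    excl = set(exclude)
    positions = []
    for q, r in hex_axial_sites(hex_radius):
        if (q, r) in excl:
            continue
        positions.append(center + axial_to_cartesian(q, r, spacing))
    positions = np.asarray(positions)
    return LatticeTruth(
        positions, [frame] * len(positions), np.full(len(positions), patch_id), spacing
    )


def make_spherical_lattice(
    radius: float, spacing: float, coverage: float = 1.0, seed: int = 0
) -> LatticeTruth:
    """Near-hexagonal packing on a sphere with radially oriented frames.

    Sites start on a Fibonacci spiral and are relaxed by pair springs
    toward uniform ``spacing``; each frame's local Y points along the
    outward radial direction and local X toward the nearest neighbor.
    With ``coverage < 1`` a random contiguous cap is retained.
    """
    if radius <= spacing:
        raise ValueError("radius must exceed spacing")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    area_per_site = np.sqrt(3.0) / 2.0 * spacing**2
    n_ideal = 4.0 * np.pi * radius**2 / area_per_site
    # Geodesic (Caspar-Klug class I) construction: subdivide an
    # icosahedron at the frequency whose site count 10 f^2 + 2 is
    # closest to the ideal hexagonal density. This gives a globally
    # coherent lattice orientation field with exactly 12 five-fold
    # defect sites, like a real quasi-hexagonal spherical shell.
    freq = max(1, int(round(np.sqrt((n_ideal - 2.0) / 10.0))))
    if n_ideal < 12:
        raise ValueError("infeasible spacing/radius combination (too few sites)")
    rng = np.random.default_rng(seed)

    g = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, g, 0), (1, g, 0), (-1, -g, 0), (1, -g, 0),
            (0, -1, g), (0, 1, g), (0, -1, -g), (0, 1, -g),
            (g, 0, -1), (g, 0, 1), (-g, 0, -1), (-g, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts[0])
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    points: dict[tuple[int, int, int], np.ndarray] = {}
    for a, b, c in faces:
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                p = (verts[a] * (freq - i - j) + verts[b] * i + verts[c] * j) / freq
                p = p / np.linalg.norm(p) * radius
                key = tuple(np.round(p / radius * 1e5).astype(int))
                points.setdefault(key, p)
    pos = np.array(list(points.values()))
    n = len(pos)

    # Pair springs polish nearest-neighbor distances toward the target
    # spacing (geodesic edge lengths vary by several percent).
    cutoff = 1.25 * spacing
    for _ in range(300):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if len(pairs) == 0:
            break
        dvec = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dist = np.linalg.norm(dvec, axis=1)
        f = 0.1 * (spacing - dist) / np.maximum(dist, 1e-9)
        step = dvec * f[:, None]
        disp = np.zeros_like(pos)
        np.add.at(disp, pairs[:, 0], step)
        np.add.at(disp, pairs[:, 1], -step)
        pos += disp
        pos *= radius / np.linalg.norm(pos, axis=1)[:, None]

    if coverage < 1.0:
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        cos_cut = 1.0 - 2.0 * coverage
        keep = (pos @ axis) / radius >= cos_cut
        pos = pos[keep]

    # Local frames: Y radial; the in-plane X axis is the local hexatic
    # (lattice) direction, so subunit orientations are locked to the
    # bonds as in a real lattice. The hexatic direction is defined mod
    # 60 degrees; the branch is chosen by parallel transport over the
    # neighbor graph (BFS from site 0) so neighboring spins vary
    # smoothly, up to the lattice defects a curved packing must contain.
    m = len(pos)
    normals = pos / np.linalg.norm(pos, axis=1)[:, None]
    tree = cKDTree(pos)
    neighbor_lists = tree.query_ball_point(pos, 1.25 * spacing)

    def hexatic_snap(i: int, proposal: np.ndarray) -> np.ndarray:
        """Hexatic direction of site i on the branch nearest ``proposal``."""
        e1 = proposal - (proposal @ normals[i]) * normals[i]
        norm = np.linalg.norm(e1)
        if norm < 1e-9:
            return proposal
        e1 /= norm
        e2 = np.cross(normals[i], e1)
        acc = 0.0 + 0.0j
        for j in neighbor_lists[i]:
            if j == i:
                continue
            v = pos[j] - pos[i]
            acc += np.exp(6j * np.arctan2(v @ e2, v @ e1))
        if abs(acc) < 1e-9:
            return e1
        psi6 = np.angle(acc) / 6.0  # in (-30 deg, 30 deg]
        return np.cos(psi6) * e1 + np.sin(psi6) * e2

    x_axes = np.zeros_like(pos)
    seen = np.zeros(m, dtype=bool)
    root_x = np.cross(normals[0], [0.0, 0.0, 1.0])
    if np.linalg.norm(root_x) < 1e-6:
        root_x = np.cross(normals[0], [1.0, 0.0, 0.0])
    x_axes[0] = hexatic_snap(0, root_x / np.linalg.norm(root_x))
    seen[0] = True

    def transport_cost(parent: int, child: int) -> tuple[float, np.ndarray]:
        axis = hexatic_snap(child, x_axes[parent])
        t = x_axes[parent] - (x_axes[parent] @ normals[child]) * normals[child]
        t /= max(np.linalg.norm(t), 1e-9)
        ang = abs(
            np.degrees(np.arctan2(t @ np.cross(normals[child], axis), t @ axis))
        )
        return ang, axis

    # Grow the branch field along a maximum-coherence spanning tree
    # (Prim's algorithm with the transport mismatch as edge cost). A
    # tangent direction field on a sphere must carry 720 degrees of
    # winding; deferring the incoherent edges pushes those unavoidable
    # branch jumps onto non-tree edges next to the 12 five-fold sites
    # instead of letting long seams form.
    import heapq

    heap = []
    for j in neighbor_lists[0]:
        if j != 0:
            cost, _ = transport_cost(0, j)
            heapq.heappush(heap, (cost, j, 0))
    while heap:
        _, j, parent = heapq.heappop(heap)
        if seen[j]:
            continue
        _, x_axes[j] = transport_cost(parent, j)
        seen[j] = True
        for k in neighbor_lists[j]:
            if not seen[k]:
                cost, _ = transport_cost(j, k)
                heapq.heappush(heap, (cost, k, j))
    for j in np.nonzero(~seen)[0]:  # isolated sites: any tangent will do
        t = np.cross(normals[j], [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-6:
            t = np.cross(normals[j], [1.0, 0.0, 0.0])
        x_axes[j] = hexatic_snap(j, t / np.linalg.norm(t))

    # Transport fronts meeting on the far side of the sphere can leave
    # whole domains on a wrong 60-degree branch. Detect branch domains
    # (components connected by smooth edges), rotate minority domains
    # wholesale when that reduces the total boundary disagreement, then
    # polish single sites. The 720 degrees of winding a tangent field
    # must carry keeps a minimal set of cuts alive; everything else
    # becomes coherent.
    def edge_angle(i: int, j: int, axes: np.ndarray) -> float:
        """Signed in-plane angle from site j's axis to site i's (degrees)."""
        t = axes[i] - (axes[i] @ normals[j]) * normals[j]
        t /= max(np.linalg.norm(t), 1e-9)
        return float(
            np.degrees(np.arctan2(t @ np.cross(normals[j], axes[j]), t @ axes[j]))
        )

    def rotate_about_normal(i: int, axis: np.ndarray, delta_deg: float) -> np.ndarray:
        s, c = np.sin(np.radians(delta_deg)), np.cos(np.radians(delta_deg))
        return c * axis + s * np.cross(normals[i], axis)

    edges = [
        (i, j)
        for i in range(m)
        for j in neighbor_lists[i]
        if j > i
    ]
    for _ in range(5):
        # domains = components of the subgraph of smooth edges
        parent = list(range(m))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in edges:
            if abs(edge_angle(i, j, x_axes)) <= 30.0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
        domains: dict[int, list[int]] = {}
        for i in range(m):
            domains.setdefault(find(i), []).append(i)
        improved = False
        for members in sorted(domains.values(), key=len):
            member_set = set(members)
            boundary = [
                (i, j)
                for i, j in edges
                if (i in member_set) != (j in member_set)
            ]
            if not boundary:
                continue
            base = sum(abs(edge_angle(i, j, x_axes)) for i, j in boundary)
            best_delta, best_cost = 0.0, base
            for delta in (60.0, -60.0, 120.0, -120.0, 180.0):
                trial = x_axes.copy()
                for k in members:
                    trial[k] = rotate_about_normal(k, trial[k], delta)
                cost = sum(abs(edge_angle(i, j, trial)) for i, j in boundary)
                if cost < best_cost - 1e-6:
                    best_delta, best_cost = delta, cost
            if best_delta != 0.0:
                for k in members:
                    x_axes[k] = rotate_about_normal(k, x_axes[k], best_delta)
                improved = True
        if not improved:
            break

    # single-site polish
    for _sweep in range(10):
        changed = 0
        for i in range(m):
            base = sum(
                abs(edge_angle(i, j, x_axes)) for j in neighbor_lists[i] if j != i
            )
            best_axis, best_cost = x_axes[i], base
            for sign in (1.0, -1.0):
                trial = x_axes.copy()
                trial[i] = rotate_about_normal(i, x_axes[i], sign * 60.0)
                cost = sum(
                    abs(edge_angle(i, j, trial)) for j in neighbor_lists[i] if j != i
                )
                if cost < best_cost - 1e-9:
                    best_axis, best_cost = trial[i], cost
            if best_axis is not x_axes[i]:
                x_axes[i] = best_axis
                changed += 1
        if changed == 0:
            break

    frames = [
        Orientation.from_matrix(
            np.stack([x_axes[i], normals[i], np.cross(x_axes[i], normals[i])], axis=1)
        )
        for i in range(m)
    ]
    return LatticeTruth(pos, frames, np.zeros(m, dtype=int), spacing)


def make_filament_lattice(
    n_repeats: int,
    spacing: float,
    curvature: float = 0.0,
    start: Sequence[float] = (0.0, 0.0, 0.0),
) -> LatticeTruth:
    """1D chain of repeats along a circular arc (``curvature`` = 1/radius).

    Local X is the in-chain tangent (the transition axis), local Y the
    in-plane arc normal; ``curvature=0`` gives a straight line along X.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if curvature < 0:
        raise ValueError("curvature must be >= 0")
    if curvature * spacing > 1.0:
        raise ValueError("curvature * spacing > 1: repeats would wrap too sharply")
    start = np.asarray(start, dtype=float)
    k = np.arange(n_repeats)
    if curvature == 0.0:
        positions = start + np.outer(k * spacing, np.array([1.0, 0.0, 0.0]))
        frames = [Orientation.identity() for _ in range(n_repeats)]
    else:
        rc = 1.0 / curvature
        theta = k * spacing * curvature
        center = start - np.array([0.0, rc, 0.0])
        positions = center + rc * np.stack(
            [np.sin(theta), np.cos(theta), np.zeros(n_repeats)], axis=1
        )
        frames = []
        for th in theta:
            cx = np.array([np.cos(th), -np.sin(th), 0.0])
            cy = np.array([np.sin(th), np.cos(th), 0.0])
            frames.append(
                Orientation.from_matrix(np.stack([cx, cy, np.cross(cx, cy)], axis=1))
            )
    return LatticeTruth(positions, frames, np.zeros(n_repeats, dtype=int), spacing)


def render_tomogram(
    truth: LatticeTruth,
    template: np.ndarray,
    volume_shape: Sequence[int],
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Sum of oriented template copies plus i.i.d. Gaussian noise.

    Each site contributes the template rotated by its frame and shifted
    to its position (trilinear interpolation); identical ``rng_seed``
    yields a bit-identical volume.
    """
    shape = tuple(int(s) for s in volume_shape)
    side = template.shape[0]
    if template.shape != (side, side, side):
        raise ValueError("template must be cubic")
    if side >= 2.0 * truth.spacing:
        raise ValueError(
            f"template side {side} must be < 2 * spacing ({2 * truth.spacing:g}) "
            "to limit overlap between neighboring sites"
        )
    bad = [
        i
        for i, p in enumerate(truth.positions)
        if np.any(p < 0) or np.any(p > np.asarray(shape) - 1)
    ]
    if bad:
        raise ValueError(
            "sites outside the volume: "
            + ", ".join(f"#{i} at {truth.positions[i].round(2).tolist()}" for i in bad)
        )

    vol = np.zeros(shape, dtype=np.float64)
    c_t = (side - 1) / 2.0
    reach = int(np.ceil((side - 1) / 2.0 * np.sqrt(3.0))) + 1
    for pos, frame in zip(truth.positions, truth.frames):
        lo = np.maximum(np.floor(pos - reach).astype(int), 0)
        hi = np.minimum(np.ceil(pos + reach).astype(int) + 1, shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        pts = np.stack([g.ravel() for g in grids]).astype(float)  # (3, M)
        local = frame.matrix.T @ (pts - pos[:, None]) + c_t
        vals = map_coordinates(
            template.astype(np.float64), local, order=1, mode="constant", cval=0.0
        )
        vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += vals.reshape(
            tuple(hi - lo)
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        vol += noise_sigma * rng.standard_normal(shape)
    return vol.astype(np.float32)


@dataclass
class Fig3Fixture:
    """The constructed two-patch hexagonal fixture behind the worked example.

    Patch A is a hex-radius-4 patch (61 sites) minus axial site (3, 1);
    patch B a disjoint 7-site patch at least four lattice steps away.
    Three seeds sit at axial (4, 0), (0, 0) and (-3, 0) of patch A; under
    the six-transition list they generate exactly 18 distinct candidate
    positions of which 14 coincide with density-bearing sites.
    """

    truth: LatticeTruth
    seeds: list[Particle]
    volume: np.ndarray
    template: np.ndarray
    transition_list: TransitionList
    spacing: float

    def reference(self, box_size: int = 16) -> np.ndarray:
        return embed_template(self.template, box_size)

    def mask(self, box_size: int = 16, radius: Optional[float] = None) -> np.ndarray:
        if radius is None:
            # Tight enough that density from the six lattice neighbors
            # stays outside the mask (soft edge included).
            radius = 0.4 * self.spacing
        return spherical_mask(box_size, radius)

    def default_params(self, cc_threshold: float = 0.5) -> ExpansionParams:
        return ExpansionParams(
            transition_list=self.transition_list,
            spacing=self.spacing,
            cc_threshold=cc_threshold,
            box_size=16,
            angular_ranges=(8.0, 8.0, 8.0),
            angular_steps=(4.0, 4.0, 4.0),
            translational_range=2.0,
            translational_step=1.0,
            max_iterations=20,
        )


FIG3_SEED_AXIALS = ((4, 0), (0, 0), (-3, 0))
FIG3_REMOVED_SITE = (3, 1)


def _fig3_layout(spacing: float):
    """Site/seed axial layout and minimal volume shape for the fixture."""
    margin = 1.5 * spacing
    a_sites = [s for s in hex_axial_sites(4) if s != FIG3_REMOVED_SITE]
    b_sites = hex_axial_sites(1)
    # Candidate positions reach one step beyond the seeds.
    reach = []
    for q, r in FIG3_SEED_AXIALS:
        for dq, dr in HEX_NEIGHBOR_OFFSETS:
            reach.append((q + dq, r + dr))
    a_extent = np.stack(
        [axial_to_cartesian(q, r, spacing) for q, r in a_sites + reach]
    )
    a_min, a_max = a_extent.min(axis=0), a_extent.max(axis=0)
    b_extent = np.stack([axial_to_cartesian(q, r, spacing) for q, r in b_sites])
    # Patch B offset along +x: >= 4 * spacing between the closest sites.
    b_offset_x = a_max[0] + 4.0 * spacing + spacing - b_extent[:, 0].min() + 0.5 * spacing
    span_x = (b_offset_x + b_extent[:, 0].max()) - a_min[0]
    span_y = max(a_max[1], b_extent[:, 1].max()) - min(a_min[1], b_extent[:, 1].min())
    min_shape = (
        int(np.ceil(span_x + 2 * margin)) + 1,
        int(np.ceil(span_y + 2 * margin)) + 1,
        int(np.ceil(2 * margin)) + 1,
    )
    return a_sites, b_sites, b_offset_x, a_min, min_shape, margin


def make_fig3_fixture(
    spacing: float = 8.0, volume_shape: Optional[Sequence[int]] = None
) -> Fig3Fixture:
    """Build the two-patch fixture with its noise-free rendered volume."""
    if spacing < 6:
        raise ValueError("spacing must be >= 6 voxels")
    a_sites, b_sites, b_offset_x, a_min, min_shape, margin = _fig3_layout(spacing)
    if volume_shape is None:
        volume_shape = min_shape
    else:
        volume_shape = tuple(int(s) for s in volume_shape)
        if any(s < m for s, m in zip(volume_shape, min_shape)):
            raise ValueError(
                f"volume shape {volume_shape} too small for the fixture; "
                f"minimal shape is {min_shape}"
            )

    a_center = np.array([margin - a_min[0], volume_shape[1] / 2.0, volume_shape[2] / 2.0])
    b_center = a_center + np.array([b_offset_x, 0.0, 0.0])
    frame = planar_frame()
    positions, frames, patch_ids = [], [], []
    for q, r in a_sites:
        positions.append(a_center + axial_to_cartesian(q, r, spacing))
        frames.append(frame)
        patch_ids.append(0)
    for q, r in b_sites:
        positions.append(b_center + axial_to_cartesian(q, r, spacing))
        frames.append(frame)
        patch_ids.append(1)
    truth = LatticeTruth(np.asarray(positions), frames, np.asarray(patch_ids), spacing)

    seeds = [
        Particle(
            position=a_center + axial_to_cartesian(q, r, spacing),
            orientation=frame,
            status="seed",
            iteration_added=0,
            tomo_name="fig3",
        )
        for q, r in FIG3_SEED_AXIALS
    ]
    template = default_template()
    volume = render_tomogram(truth, template, volume_shape, noise_sigma=0.0)
    return Fig3Fixture(
        truth=truth,
        seeds=seeds,
        volume=volume,
        template=template,
        transition_list=hexagonal_transitions(spacing),
        spacing=spacing,
    )
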