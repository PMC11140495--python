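"""Masked normalized cross-correlation and constrained rigid alignment.

Volumes are numpy arrays indexed ``[x, y, z]``. The reference holds the
template in its local frame, centered in a ``box_size`` cube; alignment
rotates the *reference* (one interpolation pass) and compares it with the
subvolume extracted around the prior position.

Angular offsets are enumerated as intrinsic rotations about the local X,
Y and Z axes (``offset = Rx(a) @ Ry(b) @ Rz(c)``), composed after the
prior orientation. Small ZYZ offsets around the identity are degenerate
(rot and psi both spin about Z and no small offset rotates about X), so
an axis-aligned offset grid is used instead; absolute orientations stay
ZYZ throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates, spline_filter
from scipy.spatial.transform import Rotation

from latticepick.core import ExpansionParams, Orientation

__all__ = ["SearchGrid", "AlignmentResult", "masked_cc", "constrained_align"]

_VAR_EPS = 1e-12


def masked_cc(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of two volumes under mask weights.

    Both volumes are mean-centered and variance-normalized using the mask
    values (in ``[0, 1]``) as weights; an absent mask means all-ones.
    Returns 0.0 when either masked variance falls below 1e-12.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
    if mask is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(mask, dtype=np.float64)
        if w.shape != a.shape:
            raise ValueError(f"mask shape {w.shape} differs from volumes {a.shape}")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("mask must have positive sum")
    ma = (w * a).sum() / wsum
    mb = (w * b).sum() / wsum
    va = (w * (a - ma) ** 2).sum() / wsum
    vb = (w * (b - mb) ** 2).sum() / wsum
    if va < _VAR_EPS or vb < _VAR_EPS:
        return 0.0
    cov = (w * (a - ma) * (b - mb)).sum() / wsum
    return float(cov / np.sqrt(va * vb))


def _axis_grid(half_range: float, step: float) -> np.ndarray:
    """Symmetric 1D grid containing 0, from -half_range to +half_range."""
    if half_range <= 0:
        return np.array([0.0])
    n = int(np.floor(half_range / step + 1e-9))
    return np.arange(-n, n + 1) * step


@dataclass
class SearchGrid:
    """Enumerated angular offsets and translational shifts around a prior pose."""

    rotations: list[Orientation]
    shifts: np.ndarray  # (n_shift, 3), voxels
    angle_norms: np.ndarray  # (n_rot,) axis-angle magnitude of each offset, degrees
    angle_axes: tuple[np.ndarray, np.ndarray, np.ndarray]  # 1D degree grids (x, y, z)
    shift_axes: np.ndarray  # 1D voxel grid shared by the three axes

    @classmethod
    def from_params(cls, params: ExpansionParams) -> "SearchGrid":
        axes_deg = [
            _axis_grid(r, s) for r, s in zip(params.angular_ranges, params.angular_steps)
        ]
        rotations: list[Orientation] = []
        norms: list[float] = []
        for a in axes_deg[0]:
            for b in axes_deg[1]:
                for c in axes_deg[2]:
                    rot = (
                        Rotation.from_euler("x", a, degrees=True)
                        * Rotation.from_euler("y", b, degrees=True)
                        * Rotation.from_euler("z", c, degrees=True)
                    )
                    rotations.append(Orientation.from_matrix(rot.as_matrix()))
                    norms.append(np.degrees(np.linalg.norm(rot.as_rotvec())))
        tgrid = _axis_grid(params.translational_range, params.translational_step)
        shifts = np.array(
            [(sx, sy, sz) for sx in tgrid for sy in tgrid for sz in tgrid]
        )
        return cls(
            rotations,
            shifts,
            np.asarray(norms),
            tuple(np.asarray(a) for a in axes_deg),
            tgrid,
        )

    def rotation_index(self, i: int) -> tuple[int, int, int]:
        nb, nc = len(self.angle_axes[1]), len(self.angle_axes[2])
        return (i // (nb * nc), (i // nc) % nb, i % nc)

    def shift_index(self, j: int) -> tuple[int, int, int]:
        nt = len(self.shift_axes)
        return (j // (nt * nt), (j // nt) % nt, j % nt)


@dataclass
class AlignmentResult:
    """Refined pose and its correlation score."""

    position: np.ndarray
    orientation: Orientation
    cc: float


def _box_grid(box_size: int) -> np.ndarray:
    """(3, box^3) offsets of box voxels relative to the box center.

    The box center is the voxel ``box_size // 2`` (integer for even and
    odd boxes alike), matching the embedding convention of references.
    """
    c = box_size // 2
    ax = np.arange(box_size) - c
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)


def check_box_fits(
    shape: Sequence[int], position: np.ndarray, box_size: int, translational_range: float
) -> bool:
    """True when the search box around ``position`` stays inside the volume."""
    half = box_size // 2 + translational_range
    pos = np.asarray(position, dtype=float)
    return bool(np.all(pos - half >= 0) and np.all(pos + half <= np.asarray(shape) - 1))


def constrained_align(
    tomo: np.ndarray,
    prior_position: Sequence[float],
    prior_orientation: Orientation,
    reference: np.ndarray,
    mask: Optional[np.ndarray],
    params: ExpansionParams,
    grid: Optional[SearchGrid] = None,
    name: str = "particle",
    refine: bool = True,
    order: int = 1,
    prefiltered: bool = False,
) -> AlignmentResult:
    """Exhaustive grid search for the best pose around a prior.

    Evaluates the masked correlation between the subvolume extracted at
    every shifted position and the reference rotated by every
    ``prior . offset`` rotation; returns the argmax. Ties are broken by
    smallest shift norm, then smallest angular offset norm, then
    enumeration order. With ``refine`` (default) the argmax is polished
    off-grid by per-axis parabolic interpolation of the correlation peak
    (shifts and angular offsets), which removes the half-step
    quantization error; the reported cc stays that of the grid argmax.

    ``order`` selects the interpolation used for subvolume extraction
    and reference rotation (1 = trilinear, 3 = cubic B-spline). With
    ``order=3`` callers may pass spline-prefiltered ``tomo`` and
    ``reference`` (``prefiltered=True``) to amortize the filtering over
    many alignments against the same volumes.
    """
    box = params.box_size
    if reference.shape != (box, box, box):
        raise ValueError(
            f"reference shape {reference.shape} does not match box_size {box}"
        )
    if mask is not None and mask.shape != (box, box, box):
        raise ValueError(f"mask shape {mask.shape} does not match box_size {box}")
    prior_position = np.asarray(prior_position, dtype=float)
    if not check_box_fits(tomo.shape, prior_position, box, params.translational_range):
        raise ValueError(
            f"search box for {name} at {prior_position.round(2).tolist()} "
            f"does not fit inside volume of shape {tuple(tomo.shape)}"
        )
    if grid is None:
        grid = SearchGrid.from_params(params)

    g = _box_grid(box)  # (3, box^3)
    n_vox = g.shape[1]
    n_rot = len(grid.rotations)
    n_shift = len(grid.shifts)
    center = np.full(3, float(box // 2))

    # Subvolumes for every shift in one interpolation call.
    pts = (
        prior_position[None, :, None]
        + grid.shifts[:, :, None]
        + g[None, :, :]
    )  # (n_shift, 3, box^3)
    coords = pts.transpose(1, 0, 2).reshape(3, -1)
    if order > 1 and not prefiltered:
        tomo = spline_filter(tomo.astype(np.float32), order=order, mode="constant")
        reference = spline_filter(
            reference.astype(np.float32), order=order, mode="constant"
        )
    subs = map_coordinates(
        tomo.astype(np.float32, copy=False),
        coords,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    B = subs.reshape(n_shift, n_vox).astype(np.float32)

    # Rotated references for every angular offset in one call. The mask
    # is applied in the box frame and is not rotated (in practice it is a
    # centered sphere, which a rotation would leave unchanged anyway).
    prior_m = prior_orientation.matrix
    rot_coords = np.empty((n_rot, 3, n_vox))
    for i, off in enumerate(grid.rotations):
        total = prior_m @ off.matrix
        rot_coords[i] = total.T @ g + center[:, None]
    rc = rot_coords.transpose(1, 0, 2).reshape(3, -1)
    A = map_coordinates(
        reference.astype(np.float32, copy=False),
        rc,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    A = A.reshape(n_rot, n_vox).astype(np.float32)
    w = (
        np.ones(n_vox, dtype=np.float32)
        if mask is None
        else np.clip(mask.reshape(-1).astype(np.float32), 0.0, 1.0)
    )
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("mask must have positive sum")

    # Weighted Pearson between every rotated reference and every shifted
    # subvolume: one GEMM for the cross terms, vector ops for the rest.
    Ea = (A @ w) / wsum  # (n_rot,)
    va = ((A**2) @ w) / wsum - Ea**2
    Eb = (B @ w) / wsum  # (n_shift,)
    vb = ((B**2) @ w) / wsum - Eb**2
    cov = ((A * w) @ B.T) / wsum - np.outer(Ea, Eb)
    denom = np.sqrt(np.maximum(np.outer(va, vb), 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(
            (va[:, None] < _VAR_EPS) | (vb[None, :] < _VAR_EPS), 0.0, cov / denom
        )
    cc = np.clip(np.nan_to_num(cc, nan=0.0), -1.0, 1.0).astype(np.float64)

    best = float(cc.max())
    ri, si = np.nonzero(cc >= best - 1e-12)
    shift_norm = np.linalg.norm(grid.shifts[si], axis=1)
    order = np.lexsort((np.arange(len(ri)), grid.angle_norms[ri], shift_norm))
    k = order[0]
    i, j = int(ri[k]), int(si[k])

    position = prior_position + grid.shifts[j]
    offset_m = grid.rotations[i].matrix
    if refine:
        position = position + _parabolic_shift(cc, grid, i, j, params)
        offset_m = _parabolic_rotation(cc, grid, i, j, params)
    return AlignmentResult(
        position=position,
        orientation=Orientation.from_matrix(prior_m @ offset_m),
        cc=float(cc[i, j]),
    )


def _vertex(c_minus: float, c_zero: float, c_plus: float) -> float:
    """Sub-step offset of a parabola through three equispaced samples."""
    denom = c_minus - 2.0 * c_zero + c_plus
    if denom >= -1e-12:
        return 0.0
    return float(np.clip(0.5 * (c_minus - c_plus) / denom, -0.6, 0.6))


def _parabolic_shift(
    cc: np.ndarray, grid: SearchGrid, i: int, j: int, params: ExpansionParams
) -> np.ndarray:
    """Subvoxel translation refinement around the argmax (per-axis parabolas)."""
    nt = len(grid.shift_axes)
    idx = list(grid.shift_index(j))
    strides = (nt * nt, nt, 1)
    delta = np.zeros(3)
    for ax in range(3):
        if 0 < idx[ax] < nt - 1:
            c_m = cc[i, j - strides[ax]]
            c_p = cc[i, j + strides[ax]]
            delta[ax] = _vertex(c_m, cc[i, j], c_p) * params.translational_step
    return delta


def _parabolic_rotation(
    cc: np.ndarray, grid: SearchGrid, i: int, j: int, params: ExpansionParams
) -> np.ndarray:
    """Sub-step angular refinement of the offset rotation at the argmax."""
    na, nb, nc = (len(a) for a in grid.angle_axes)
    ia, ib, ic = grid.rotation_index(i)
    strides = (nb * nc, nc, 1)
    idx = (ia, ib, ic)
    sizes = (na, nb, nc)
    angles = [grid.angle_axes[ax][idx[ax]] for ax in range(3)]
    for ax in range(3):
        if 0 < idx[ax] < sizes[ax] - 1:
            c_m = cc[i - strides[ax], j]
            c_p = cc[i + strides[ax], j]
            angles[ax] += _vertex(c_m, cc[i, j], c_p) * params.angular_steps[ax]
    return (
        Rotation.from_euler("x", angles[0], degrees=True)
        * Rotation.from_euler("y", angles[1], degrees=True)
        * Rotation.from_euler("z", angles[2], degrees=True)
    ).as_matrix()
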