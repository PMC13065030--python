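"""6-DOF rigid-body registration with a least-squares intensity cost.

Aligns a moving volume (pre-contrast) to a fixed volume (post-contrast)
acquired in the same session, so only small rotations/translations are
expected (capture range about ±10 mm / ±10°).  The cost is the mean squared
intensity difference on the fixed grid, minimized by a derivative-free
Powell search over the six parameters through a Gaussian multi-resolution
pyramid (coarse to fine).

Convention: the transform maps moving-space world coordinates to fixed
space,  y = R (x - c) + c + t,  with R an intrinsic x-y-z Euler rotation
about the volume center c, angles in degrees, translations in mm.  World
coordinates are voxel indices scaled by the voxel size (RAS+, origin at
voxel 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees about x, y, z) + translation (mm), about ``center``."""

    rotations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=tuple(float(c) for c in center))

    @classmethod
    def from_params(cls, params, center) -> "RigidTransform":
        p = np.asarray(params, dtype=float)
        return cls(tuple(p[:3]), tuple(p[3:6]), tuple(float(c) for c in center))

    @property
    def params(self) -> np.ndarray:
        return np.array(self.rotations + self.translations, dtype=float)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on world coordinates (mm)."""
        R = _rotation_matrix(*self.rotations)
        c = np.asarray(self.center)
        t = np.asarray(self.translations)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def inverse(self) -> "RigidTransform":
        """Exact inverse as another rigid transform about the same center."""
        R = _rotation_matrix(*self.rotations)
        # y = R(x-c)+c+t  =>  x = R^T(y-c)+c - R^T t; express as rigid about c
        Rinv = R.T
        # Euler extraction for the intrinsic x-y-z convention
        # (R = Rx @ Ry @ Rz): R[0,2] = sin(ry), R[0,1] = -cos(ry) sin(rz),
        # R[1,2] = -sin(rx) cos(ry)
        ry = np.degrees(np.arcsin(np.clip(Rinv[0, 2], -1.0, 1.0)))
        rx = np.degrees(np.arctan2(-Rinv[1, 2], Rinv[2, 2]))
        rz = np.degrees(np.arctan2(-Rinv[0, 1], Rinv[0, 0]))
        t_inv = -Rinv @ np.asarray(self.translations)
        return RigidTransform((rx, ry, rz), tuple(t_inv), self.center)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map Nx3 world points through the transform."""
        M = self.matrix()
        pts = np.atleast_2d(pts)
        return pts @ M[:3, :3].T + M[:3, 3]


def volume_center_world(shape, voxel_size) -> tuple[float, float, float]:
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    return tuple(vs * (np.asarray(shape) - 1) / 2.0)


def resample(
    volume: np.ndarray,
    transform: RigidTransform,
    voxel_size: float | tuple[float, float, float] = 1.0,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample ``volume`` onto the fixed grid through ``transform``.

    ``interpolation`` is ``trilinear`` for intensity volumes or ``nearest``
    for label volumes; trilinear on an integer-typed (label) volume is
    rejected.  Out-of-field voxels are set to 0 (background).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if interpolation == "trilinear" and np.issubdtype(volume.dtype, np.integer):
        raise ValueError("trilinear interpolation is invalid for label volumes; use nearest")
    order = 1 if interpolation == "trilinear" else 0
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    A = np.diag(vs)
    Ainv = np.diag(1.0 / vs)
    R = _rotation_matrix(*transform.rotations)
    c = np.asarray(transform.center)
    t = np.asarray(transform.translations)
    # source voxel index for each output voxel: i_m = A^-1 (R^T (A i_f - c - t) + c)
    M = Ainv @ R.T @ A
    offset = Ainv @ (c - R.T @ (c + t))
    return ndimage.affine_transform(
        volume, M, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )


def _pyramid(
    volume: np.ndarray, levels: int, finest_sigma: float = 1.0
) -> list[tuple[np.ndarray, float]]:
    """Smoothed/decimated copies, coarsest first; second element is the
    voxel-size multiplier of the level.

    The finest level is also mildly smoothed (``finest_sigma`` voxels):
    the SSD of hard-edged volumes is not smooth under subvoxel shifts, and
    its minimum can be displaced by interpolation artifacts; band-limiting
    both volumes removes that bias (real acquisitions are band-limited
    already)."""
    out = []
    for lvl in range(levels - 1, -1, -1):
        factor = 2**lvl
        if factor == 1:
            sm = (
                ndimage.gaussian_filter(volume.astype(float), sigma=finest_sigma)
                if finest_sigma > 0
                else volume
            )
            out.append((sm, 1.0))
        else:
            sm = ndimage.gaussian_filter(volume.astype(float), sigma=factor / 2.0)
            out.append((sm[::factor, ::factor, ::factor], float(factor)))
    return out


def _transform_to_grid(transform: RigidTransform, voxel_size):
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    A, Ainv = np.diag(vs), np.diag(1.0 / vs)
    R = _rotation_matrix(*transform.rotations)
    c = np.asarray(transform.center)
    t = np.asarray(transform.translations)
    return Ainv @ R.T @ A, Ainv @ (c - R.T @ (c + t))


def _ssd(
    moving, fixed, params, center, voxel_size, order: int = 1, stride: int = 1
) -> float:
    # `moving` must be spline-prefiltered by the caller when order > 1
    tr = RigidTransform.from_params(params, center)
    M, offset = _transform_to_grid(tr, voxel_size)
    if stride > 1:  # sample the cost on a decimated fixed grid
        fixed = fixed[::stride, ::stride, ::stride]
        M = M * stride
    resampled = ndimage.affine_transform(
        moving, M, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False, output_shape=fixed.shape,
    )
    d = resampled - fixed
    return float(np.mean(d * d))


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    voxel_size: float | tuple[float, float, float] = 1.0,
    levels: int = 3,
    xtol: float = 1e-3,
    capture_range: tuple[float, float] = (10.0, 10.0),
    finest_sigma: float = 1.0,
) -> tuple[RigidTransform, dict]:
    """Estimate the rigid transform mapping ``moving`` into ``fixed`` space.

    Multi-resolution Powell minimization of the mean squared intensity
    difference, initialized at identity; rotations are bounded to
    ±``capture_range[0]`` degrees and translations to ±``capture_range[1]``
    mm.  Returns the transform and an info dict with the cost bookkeeping
    (``cost_initial``, ``cost_final``, per-level traces, and ``status``:
    ``converged``, or ``failed`` when the optimum does not improve on the
    initialization, in which case the identity transform is returned).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed volumes must share a grid shape")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    center = volume_center_world(fixed.shape, vs)
    mov_pyr = _pyramid(moving, levels, finest_sigma)
    fix_pyr = _pyramid(fixed, levels, finest_sigma)

    rot_max, trans_max = capture_range
    bounds = [(-rot_max, rot_max)] * 3 + [(-trans_max, trans_max)] * 3
    params = np.zeros(6)
    level_costs = []
    for (mov_l, factor), (fix_l, _) in zip(mov_pyr, fix_pyr):
        vs_l = vs * factor
        center_l = volume_center_world(fix_l.shape, vs_l)
        # cubic-spline image model at the finest level: the trilinear SSD
        # of voxelized edges has spurious minima at subvoxel offsets; the
        # cost is sampled on a stride-2 subgrid there to keep it cheap
        order = 3 if factor == 1.0 else 1
        stride = 2 if factor == 1.0 else 1
        mov_s = ndimage.spline_filter(mov_l, order=3) if order == 3 else mov_l
        fun = lambda p: _ssd(mov_s, fix_l, p, center_l, vs_l, order, stride)
        c_in = fun(params)
        res = optimize.minimize(
            fun, params, method="Powell", bounds=bounds,
            options={"xtol": xtol, "ftol": 1e-9},
        )
        if res.fun <= c_in:
            params = res.x
            c_out = float(res.fun)
        else:  # keep incoming params: cost may never increase across levels
            c_out = c_in
        level_costs.append({"factor": factor, "cost_in": c_in, "cost_out": c_out})

    cost_initial = _ssd(moving, fixed, np.zeros(6), center, vs)
    cost_final = _ssd(moving, fixed, params, center, vs)
    if cost_final > cost_initial * (1.0 + 1e-6):
        return RigidTransform.identity(center), {
            "status": "failed",
            "cost_initial": cost_initial,
            "cost_final": cost_initial,
            "levels": level_costs,
        }
    return RigidTransform.from_params(params, center), {
        "status": "converged",
        "cost_initial": cost_initial,
        "cost_final": cost_final,
        "levels": level_costs,
    }


def save_transform(path, transform: RigidTransform) -> None:
    """Write the 4x4 homogeneous world-coordinate matrix as plain text."""
    np.savetxt(path, transform.matrix(), fmt="%.10f")


def load_transform_matrix(path) -> np.ndarray:
    M = np.loadtxt(path)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {M.shape}")
    return M
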