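"""Shared acquisition-geometry primitives.

Lab frame convention: the beam travels along +x, the scanning stage moves
the specimen in y (horizontal, transverse) and z (vertical).  The specimen
is tilted by ``alpha`` about the lab y axis and then rotated by ``omega``
about its own z axis, so a point ``v`` in specimen coordinates sits at
``R_y(alpha) @ R_z(omega) @ v`` in the lab.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "rot_y",
    "rot_z",
    "lab_to_sample_matrix",
    "fibonacci_sphere",
    "JosephProjector",
]


def rot_z(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about z."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about y."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def lab_to_sample_matrix(tilt_deg: float, rot_deg: float) -> np.ndarray:
    """Matrix mapping lab-frame vectors into the specimen frame."""
    return rot_z(-rot_deg) @ rot_y(-tilt_deg)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform directions on the unit sphere, shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


class JosephProjector:
    """Parallel-beam ray integrator over a voxel grid (Joseph's method).

    Samples each ray at ``step_frac`` voxel intervals with trilinear
    interpolation and assembles the result as a sparse matrix so the same
    weights serve both forward projection and its exact adjoint.

    Voxel (i, j, k) is centred at ``(idx - (n - 1) / 2) * voxel_size`` mm in
    specimen coordinates; volumes are flattened C-order.
    """

    def __init__(self, shape: tuple[int, int, int], voxel_size_mm: float,
                 step_frac: float = 0.5):
        self.shape = tuple(int(s) for s in shape)
        if len(self.shape) != 3:
            raise ValueError("shape must be 3D")
        if voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        self.voxel_size_mm = float(voxel_size_mm)
        self.step_mm = step_frac * self.voxel_size_mm
        self.n_vox = int(np.prod(self.shape))
        self._cache: dict = {}

    def ray_offsets(self, n_y: int, n_z: int, step_mm: float):
        """Centred (y, z) scan offsets in mm for an n_y x n_z raster."""
        y = (np.arange(n_y) - (n_y - 1) / 2.0) * step_mm
        z = (np.arange(n_z) - (n_z - 1) / 2.0) * step_mm
        return y, z

    def ray_matrix(self, tilt_deg: float, rot_deg: float,
                   y_offsets_mm: np.ndarray, z_offsets_mm: np.ndarray) -> sparse.csr_matrix:
        """Sparse (n_rays, n_vox) line-integral operator for one projection.

        Rays are ordered with the y offset as the fast axis flattened last,
        i.e. row = iy * n_z + iz.
        """
        key = (round(float(tilt_deg), 9), round(float(rot_deg), 9),
               y_offsets_mm.tobytes(), z_offsets_mm.tobytes())
        hit = self._cache.get(key)
        if hit is not None:
            return hit

        nx, ny, nz = self.shape
        half = (np.array(self.shape, dtype=float) - 1.0) / 2.0
        extent = 0.5 * np.linalg.norm(np.array(self.shape)) * self.voxel_size_mm
        # symmetric about t=0 so opposing projections sample identical points
        n_half = int(np.ceil((extent + self.voxel_size_mm) / self.step_mm))
        t = np.arange(-n_half, n_half + 1) * self.step_mm

        yy, zz = np.meshgrid(y_offsets_mm, z_offsets_mm, indexing="ij")
        n_rays = yy.size
        # lab-frame sample points: (n_rays, n_t, 3)
        pts = np.empty((n_rays, t.size, 3))
        pts[:, :, 0] = t[None, :]
        pts[:, :, 1] = yy.ravel()[:, None]
        pts[:, :, 2] = zz.ravel()[:, None]

        M = lab_to_sample_matrix(tilt_deg, rot_deg)
        idx = pts @ M.T / self.voxel_size_mm + half[None, None, :]

        inside = np.all((idx >= 0.0) & (idx <= np.array(self.shape) - 1.0), axis=2)
        rows_base = np.broadcast_to(np.arange(n_rays)[:, None], inside.shape)[inside]
        p = idx[inside]  # (n_pts, 3) fractional voxel coords

        i0 = np.minimum(np.floor(p).astype(np.int64),
                        np.maximum(np.array(self.shape) - 2, 0))
        i0 = np.maximum(i0, 0)
        f = p - i0
        # size-1 axes: the +1 corner gets zero weight; clamp its index in-range
        ix1 = np.minimum(i0[:, 0] + 1, nx - 1)
        iy1 = np.minimum(i0[:, 1] + 1, ny - 1)
        iz1 = np.minimum(i0[:, 2] + 1, nz - 1)

        rows = []
        cols = []
        vals = []
        for dx in (0, 1):
            wx = f[:, 0] if dx else 1.0 - f[:, 0]
            for dy in (0, 1):
                wy = f[:, 1] if dy else 1.0 - f[:, 1]
                for dz in (0, 1):
                    wz = f[:, 2] if dz else 1.0 - f[:, 2]
                    w = wx * wy * wz
                    cx = ix1 if dx else i0[:, 0]
                    cy = iy1 if dy else i0[:, 1]
                    cz = iz1 if dz else i0[:, 2]
                    c = (cx * ny + cy) * nz + cz
                    rows.append(rows_base)
                    cols.append(c)
                    vals.append(w * self.step_mm)
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_rays, self.n_vox),
        ).tocsr()
        self._cache[key] = mat
        return mat
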