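"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-implement the mathematical definitions with
different code (explicit loops, map_coordinates sampling) so they stay
independent of the package's vectorised/sparse paths they are checking.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mmxct.phantom import Phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phantom_from_mu(mu: np.ndarray, voxel_size_mm: float) -> Phantom:
    """Phantom carrying only an attenuation field (everything else zero)."""
    z = np.zeros_like(mu)
    return Phantom(
        voxel_size_mm=voxel_size_mm,
        collagen_density=z.copy(),
        orientation=np.zeros(mu.shape + (3,)),
        anisotropy=z.copy(),
        fibril_diameter=z.copy(),
        fe_conc=z.copy(),
        zn_conc=z.copy(),
        mu=mu.astype(float),
        support_mask=mu > 0,
    )


def antialiased_disc(n: int, radius_voxels: float, supersample: int = 8):
    """Fractional-coverage disc on an n x n grid (centre of the grid)."""
    idx = (np.arange(n * supersample) + 0.5) / supersample - n / 2.0
    X, Y = np.meshgrid(idx, idx, indexing="ij")
    fine = (X ** 2 + Y ** 2 <= radius_voxels ** 2).astype(float)
    return fine.reshape(n, supersample, n, supersample).mean(axis=(1, 3))


def oracle_line_integrals(volume: np.ndarray, voxel_size_mm: float,
                          tilt_deg: float, rot_deg: float,
                          y_offsets_mm: np.ndarray,
                          z_offsets_mm: np.ndarray) -> np.ndarray:
    """Independent Joseph-style line integrator (map_coordinates based).

    Same discretisation convention as the package (half-voxel steps,
    symmetric about t=0, trilinear interpolation), different code path.
    """
    shape = np.array(volume.shape, dtype=float)
    half = (shape - 1.0) / 2.0
    step = 0.5 * voxel_size_mm
    extent = 0.5 * float(np.linalg.norm(shape)) * voxel_size_mm
    n_half = int(np.ceil((extent + voxel_size_mm) / step))
    t = np.arange(-n_half, n_half + 1) * step

    a_t = np.deg2rad(tilt_deg)
    a_r = np.deg2rad(rot_deg)
    Ry = np.array([[np.cos(a_t), 0, np.sin(a_t)],
                   [0, 1, 0],
                   [-np.sin(a_t), 0, np.cos(a_t)]])
    Rz = np.array([[np.cos(a_r), -np.sin(a_r), 0],
                   [np.sin(a_r), np.cos(a_r), 0],
                   [0, 0, 1]])
    M = Rz.T @ Ry.T  # lab -> sample for the package's tilt-then-rotate order

    out = np.empty((y_offsets_mm.size, z_offsets_mm.size))
    for iy, y in enumerate(y_offsets_mm):
        for iz, z in enumerate(z_offsets_mm):
            pts_lab = np.column_stack([t, np.full_like(t, y),
                                       np.full_like(t, z)])
            pts = pts_lab @ M.T / voxel_size_mm + half
            vals = ndimage.map_coordinates(volume, pts.T, order=1, cval=0.0)
            out[iy, iz] = vals.sum() * step
    return out


def oracle_fbp(sinogram: np.ndarray, angles_deg: np.ndarray, spacing: float,
               window: str = "hamming") -> np.ndarray:
    """Direct back-projection + frequency-domain filter, loop-based."""
    n_det = sinogram.shape[1]
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    freqs = np.fft.fftfreq(n_pad, d=spacing)
    filt = np.abs(freqs)
    if window == "hamming":
        filt = filt * (0.54 + 0.46 * np.cos(np.pi * freqs / (0.5 / spacing)))
    coords = (np.arange(n_det) - (n_det - 1) / 2.0) * spacing
    recon = np.zeros((n_det, n_det))
    for row, ang in zip(sinogram, np.deg2rad(angles_deg)):
        q = np.real(np.fft.ifft(np.fft.fft(row, n_pad) * filt))[:n_det]
        for i, x in enumerate(coords):
            for j, y in enumerate(coords):
                r = x * np.sin(ang) + y * np.cos(ang)
                recon[i, j] += np.interp(r, coords, q, left=0.0, right=0.0)
    return recon * np.pi / angles_deg.size
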