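"""Tomographic reconstruction: scalar FBP and rank-2 tensor tomography.

Conventions match the forward simulators: tilt-0 parallel-beam slices with
detector coordinate ``r = x sin(omega) + y cos(omega)`` for rotation angle
omega, and Joseph ray tracing (trilinear sampling at half-voxel steps) for
the tensor system matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import JosephProjector, lab_to_sample_matrix
from .scatter_model import (anisotropy_degree_field, probe_coefficients,
                            sym6_to_matrix)

__all__ = [
    "ScalarVolume",
    "Rank2TensorField",
    "fbp",
    "fbp_volume",
    "reconstruct_mu",
    "reconstruct_tensor",
    "principal_orientation",
    "mean_scattering_volume",
]


@dataclass
class ScalarVolume:
    """Scalar field on the reconstruction grid with a validity mask."""

    values: np.ndarray
    voxel_size_mm: float
    label: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask/values shape mismatch")


@dataclass
class Rank2TensorField:
    """Per-voxel packed symmetric tensors plus the solver's objective log."""

    sym6: np.ndarray              # (nx, ny, nz, 6)
    voxel_size_mm: float
    objective: np.ndarray = field(default_factory=lambda: np.zeros(0))
    single_tilt_warning: bool = False


# ---------------------------------------------------------------------------
# Filtered back-projection


def _ramp_filter(n_pad: int, spacing: float, window: str) -> np.ndarray:
    freqs = np.fft.fftfreq(n_pad, d=spacing)
    filt = np.abs(freqs)
    if window == "hamming":
        f_nyq = 0.5 / spacing
        filt = filt * (0.54 + 0.46 * np.cos(np.pi * freqs / f_nyq))
    elif window != "ramp":
        raise ValueError(f"unknown filter window {window!r}")
    return filt


def filter_sinogram(sinogram: np.ndarray, spacing: float,
                    window: str = "hamming") -> np.ndarray:
    """Frequency-domain ramp (optionally Hamming-windowed) filtering."""
    sinogram = np.asarray(sinogram, dtype=float)
    n_det = sinogram.shape[-1]
    n_pad = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    filt = _ramp_filter(n_pad, spacing, window)
    spec = np.fft.fft(sinogram, n=n_pad, axis=-1) * filt
    return np.real(np.fft.ifft(spec, axis=-1))[..., :n_det]


def fbp(sinogram: np.ndarray, angles_deg: np.ndarray, spacing: float = 1.0,
        window: str = "hamming") -> np.ndarray:
    """Filtered back-projection of one slice.

    ``sinogram`` has shape (n_angles, n_det) with detector samples at
    ``(i - (n_det - 1)/2) * spacing`` and line integrals measured along
    ``x sin(omega) + y cos(omega) = r``.  Returns an (n_det, n_det) image on
    the same spacing.
    """
    sinogram = np.asarray(sinogram, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if sinogram.ndim != 2 or sinogram.shape[0] != angles_deg.size:
        raise ValueError("sinogram rows must match the number of angles")
    if angles_deg.size < 2:
        raise ValueError("need at least two projection angles")
    n_det = sinogram.shape[1]
    filtered = filter_sinogram(sinogram, spacing, window)

    coords = (np.arange(n_det) - (n_det - 1) / 2.0) * spacing
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    recon = np.zeros((n_det, n_det))
    for ang, row in zip(np.deg2rad(angles_deg), filtered):
        r = X * np.sin(ang) + Y * np.cos(ang)
        recon += np.interp(r, coords, row, left=0.0, right=0.0)
    return recon * (np.pi / angles_deg.size)


def fbp_volume(sinogram: np.ndarray, angles_deg: np.ndarray, spacing: float,
               window: str = "hamming") -> np.ndarray:
    """Slice-wise FBP of a (n_angles, n_y, n_z) sinogram -> (n_y, n_y, n_z)."""
    sinogram = np.asarray(sinogram, dtype=float)
    n_ang, n_y, n_z = sinogram.shape
    out = np.empty((n_y, n_y, n_z))
    for k in range(n_z):
        out[:, :, k] = fbp(sinogram[:, :, k], angles_deg, spacing, window)
    return out


def reconstruct_mu(transmission: np.ndarray, angles_deg: np.ndarray,
                   voxel_size_mm: float, window: str = "hamming") -> ScalarVolume:
    """FBP of -ln(T) per slice; returns mu in mm^-1 on the scan grid."""
    T = np.asarray(transmission, dtype=float)
    if np.any(T <= 0) or np.any(T > 1.0 + 1e-12):
        raise ValueError("transmission must lie in (0, 1]")
    vol = fbp_volume(-np.log(T), angles_deg, voxel_size_mm, window)
    return ScalarVolume(values=vol, voxel_size_mm=voxel_size_mm,
                        label="transmission-mu")


# ---------------------------------------------------------------------------
# Rank-2 tensor tomography


def _segment_directions(n_segments: int, tilt_deg: float,
                        rot_deg: float) -> np.ndarray:
    """Sample-frame probe directions for the azimuthal segment centres."""
    phi = (np.arange(n_segments) + 0.5) * 2.0 * np.pi / n_segments
    u_lab = np.column_stack([np.zeros(n_segments), np.cos(phi), np.sin(phi)])
    return u_lab @ lab_to_sample_matrix(tilt_deg, rot_deg).T


def reconstruct_tensor(sinogram, q_index: int, grid_shape: tuple[int, int, int],
                       voxel_size_mm: float, n_iter: int = 200,
                       init_step: float = 1.0, tol: float = 0.0,
                       method: str = "cg", clip_eigenvalues: bool = False,
                       verbose: bool = False) -> Rank2TensorField:
    """Least-squares rank-2 tensor field from azimuthal sinograms.

    Minimises sum over measurements of
    ``(d - integral_ray u^T A(v) u dl)^2`` from an isotropic-mean start.
    ``method='cg'`` (default) is Polak-Ribiere conjugate gradient with exact
    line search on the quadratic objective; ``method='gd'`` is plain
    preconditioned gradient descent with backtracking.  Both decrease the
    objective monotonically.  ``sinogram`` is an ``AzimuthalSinogram``
    (self-attenuation corrected measurements are taken at ``q_index``).
    """
    frames = sinogram.frames
    tilts = {f.tilt_deg for f in frames}
    single_tilt = len(tilts) < 2

    projector = JosephProjector(grid_shape, voxel_size_mm)
    n_vox = projector.n_vox
    mats, data, coeffs = [], [], []
    for i, fr in enumerate(frames):
        S = projector.ray_matrix(fr.tilt_deg, fr.rotation_deg,
                                 fr.y_offsets_mm, fr.z_offsets_mm)
        d = np.asarray(sinogram.intensities[i][:, :, :, q_index], dtype=float)
        T = np.asarray(sinogram.transmission[i], dtype=float)
        d = d / np.maximum(T, 1e-9)[:, :, None]   # self-attenuation correction
        scale = sinogram.exposure_s * sinogram.flux * sinogram.counts_per_unit
        mats.append(S)
        data.append(d.reshape(-1, d.shape[-1]) / scale)  # (n_rays, n_seg)
        coeffs.append(probe_coefficients(
            _segment_directions(d.shape[-1], fr.tilt_deg, fr.rotation_deg)))

    # isotropic start: A = c I with c from a 1-parameter least squares
    num = 0.0
    den = 0.0
    ones = np.ones(n_vox)
    for S, d in zip(mats, data):
        p0 = S @ ones
        num += float(p0 @ d.sum(axis=1))
        den += float((p0 ** 2).sum() * d.shape[1])
    c0 = num / den if den > 0 else 0.0
    A = np.zeros((n_vox, 6))
    A[:, :3] = c0

    def objective_and_grad(A, want_grad=True):
        obj = 0.0
        grad = np.zeros_like(A) if want_grad else None
        for S, d, cf in zip(mats, data, coeffs):
            fields = A @ cf.T                # (n_vox, n_seg)
            pred = S @ fields                # (n_rays, n_seg)
            resid = pred - d
            obj += float((resid ** 2).sum())
            if want_grad:
                back = S.T @ resid           # (n_vox, n_seg)
                grad += 2.0 * (back @ cf)
        return obj, grad

    def hessian_dot(P):
        out = np.zeros_like(P)
        for S, cf in zip(mats, coeffs):
            out += 2.0 * (S.T @ (S @ (P @ cf.T))) @ cf
        return out

    obj, grad = objective_and_grad(A)
    log = [obj]
    if method == "cg":
        direction = -grad
        for it in range(n_iter):
            Hd = hessian_dot(direction)
            denom = float((direction * Hd).sum())
            slope = float((grad * direction).sum())
            if denom <= 0.0 or slope >= 0.0:
                break
            alpha = -slope / denom
            A = A + alpha * direction
            new_grad = grad + alpha * Hd
            obj = obj + alpha * slope + 0.5 * alpha * alpha * denom
            log.append(obj)
            if verbose and it % 20 == 0:
                print(f"iter {it}: objective {obj:.6g}")
            if tol > 0 and (log[-2] - log[-1]) < tol * log[0]:
                grad = new_grad
                break
            beta = max(float((new_grad * (new_grad - grad)).sum())
                       / max(float((grad * grad).sum()), 1e-300), 0.0)
            direction = -new_grad + beta * direction
            grad = new_grad
        obj, _ = objective_and_grad(A, want_grad=False)
        log[-1] = obj
    elif method == "gd":
        # Jacobi preconditioner: diagonal of the normal operator, equalising
        # edge/interior voxel sensitivity
        diag = np.zeros((n_vox, 6))
        for S, cf in zip(mats, coeffs):
            col = np.asarray(S.multiply(S).sum(axis=0)).ravel()
            diag += np.outer(col, (cf ** 2).sum(axis=0))
        precond = 1.0 / (2.0 * diag + 1e-8 * diag.max())
        step = init_step
        for it in range(n_iter):
            direction = precond * grad
            slope = float((grad * direction).sum())
            if slope <= 0.0:
                break
            accepted = False
            for _ in range(30):
                cand = A - step * direction
                new_obj, _ = objective_and_grad(cand, want_grad=False)
                if new_obj <= obj - 1e-4 * step * slope:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            A = cand
            obj = new_obj
            log.append(obj)
            if verbose and it % 20 == 0:
                print(f"iter {it}: objective {obj:.6g}")
            if tol > 0 and (log[-2] - log[-1]) < tol * log[0]:
                break
            _, grad = objective_and_grad(A)
            step *= 2.0
    else:
        raise ValueError(f"unknown tensor solver method {method!r}")

    sym6 = A.reshape(grid_shape + (6,))
    if clip_eigenvalues:
        M = sym6_to_matrix(sym6.reshape(-1, 6))
        w, v = np.linalg.eigh(M)
        w = np.maximum(w, 0.0)
        M = np.einsum("nij,nj,nkj->nik", v, w, v)
        from .scatter_model import matrix_to_sym6
        sym6 = matrix_to_sym6(M).reshape(grid_shape + (6,))
    return Rank2TensorField(sym6=sym6, voxel_size_mm=voxel_size_mm,
                            objective=np.array(log),
                            single_tilt_warning=single_tilt)


def principal_orientation(tensor_field: Rank2TensorField,
                          n_dirs: int = 10_000):
    """Top eigenvector per voxel plus the anisotropy-degree volume.

    Eigenvectors are canonicalised to z >= 0 (ties broken by y >= 0 then
    x >= 0).  Voxels whose tensor has non-positive directional mean are
    masked out.
    """
    shape = tensor_field.sym6.shape[:3]
    flat = tensor_field.sym6.reshape(-1, 6)
    M = sym6_to_matrix(flat)
    w, v = np.linalg.eigh(M)                 # ascending eigenvalues
    top = v[:, :, 2]
    flip = (top[:, 2] < 0) | ((top[:, 2] == 0) & (top[:, 1] < 0)) \
        | ((top[:, 2] == 0) & (top[:, 1] == 0) & (top[:, 0] < 0))
    top[flip] *= -1.0
    degree = anisotropy_degree_field(flat, n_dirs=n_dirs)
    valid = np.isfinite(degree)
    degree = np.where(valid, degree, 0.0)
    orientation = np.where(valid[:, None], top, 0.0).reshape(shape + (3,))
    vol = ScalarVolume(values=degree.reshape(shape),
                       voxel_size_mm=tensor_field.voxel_size_mm,
                       label="anisotropy-degree", mask=valid.reshape(shape))
    return orientation, vol


def _tilt0_sinogram(sinogram, q_index=None):
    """Stack tilt-0 frames into (n_rot, n_y, n_z[, ...]) plus their angles."""
    rows, angles, trans = [], [], []
    for i, fr in enumerate(sinogram.frames):
        if fr.tilt_deg != 0.0:
            continue
        arr = np.asarray(sinogram.intensities[i], dtype=float)
        rows.append(arr if q_index is None else arr[..., q_index])
        trans.append(np.asarray(sinogram.transmission[i], dtype=float))
        angles.append(fr.rotation_deg)
    if not rows:
        raise ValueError("no tilt-0 frames in sinogram")
    return np.stack(rows), np.array(angles), np.stack(trans)


def mean_scattering_volume(sinogram, q_index: int,
                           window: str = "hamming") -> ScalarVolume:
    """FBP of the segment-averaged, self-attenuation-corrected tilt-0 data."""
    stack, angles, T = _tilt0_sinogram(sinogram, q_index=None)
    seg_mean = stack[..., q_index].mean(axis=3)   # (n_rot, n_y, n_z)
    seg_mean = seg_mean / np.maximum(T, 1e-9)
    scale = sinogram.exposure_s * sinogram.flux * sinogram.counts_per_unit
    vol = fbp_volume(seg_mean / scale, angles, sinogram.step_mm, window)
    return ScalarVolume(values=vol, voxel_size_mm=sinogram.step_mm,
                        label="mean-scattering")


def q_resolved_volumes(sinogram, window: str = "hamming") -> np.ndarray:
    """FBP per q bin of segment-averaged tilt-0 data -> (n_q, n_y, n_y, n_z)."""
    stack, angles, T = _tilt0_sinogram(sinogram)
    scale = sinogram.exposure_s * sinogram.flux * sinogram.counts_per_unit
    seg_mean = stack.mean(axis=3) / np.maximum(T[..., None], 1e-9) / scale
    n_q = seg_mean.shape[-1]
    vols = [fbp_volume(seg_mean[..., iq], angles, sinogram.step_mm, window)
            for iq in range(n_q)]
    return np.stack(vols)
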