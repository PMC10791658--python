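"""Collagen small-angle scattering model.

q-space conversions, the cylinder + axial-period intensity profile, the
rank-2 (tensor) anisotropy model probed along unit directions, azimuthal
integration of 2D patterns, and bounded least-squares fitting of the fibril
parameters (axial period D and diameter 2R).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from ._geom import fibonacci_sphere

HC_KEV_NM = 1.239842  # h*c in keV.nm

__all__ = [
    "HC_KEV_NM",
    "BeamSpec",
    "CollagenProfileParams",
    "FibrilFitResult",
    "SegmentedProfile",
    "wavelength_from_energy",
    "q_from_angle",
    "collagen_profile",
    "fit_fibril_params",
    "sym6_to_matrix",
    "matrix_to_sym6",
    "tensor_probe",
    "anisotropy_degree",
    "integrate_pattern_2d",
]


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in nm for an energy in keV."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic beam: energy in keV, wavelength derived."""

    energy_kev: float = 12.4

    def __post_init__(self):
        if self.energy_kev <= 0:
            raise ValueError("energy must be positive")

    @property
    def wavelength_nm(self) -> float:
        return wavelength_from_energy(self.energy_kev)


def q_from_angle(theta_rad, wavelength_nm: float):
    """Momentum transfer q = 4 pi sin(theta/2) / lambda in nm^-1."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(theta < 0) or np.any(theta >= np.pi):
        raise ValueError("scattering angle must lie in [0, pi)")
    out = 4.0 * np.pi * np.sin(theta / 2.0) / wavelength_nm
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fibril profile model


@dataclass(frozen=True)
class CollagenProfileParams:
    """Parameters of the axially periodic cylinder-bundle intensity model.

    D is the axial period (nm), R the fibril radius (nm), f the overlap
    fraction of the two-level axial density, a_hex an optional hexagonal
    packing distance (nm) adding one interference peak, peak_width the sigma
    of the Gaussian axial reflections (nm^-1).
    """

    D: float = 65.0
    R: float = 25.0
    f: float = 0.53
    scale: float = 1.0
    background: float = 0.0
    peak_width: float = 0.02
    a_hex: float | None = None
    hex_amp: float = 0.0

    def validate(self) -> None:
        if not (55.0 <= self.D <= 75.0):
            raise ValueError(f"axial period D={self.D} outside [55, 75] nm")
        if not (15.0 <= self.R <= 40.0):
            raise ValueError(f"fibril radius R={self.R} outside [15, 40] nm")
        if not (0.0 < self.f < 1.0):
            raise ValueError("overlap fraction f must lie in (0, 1)")
        if self.scale < 0 or self.background < 0:
            raise ValueError("scale and background must be non-negative")
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")


def _cylinder_factor(q, R):
    """[2 J1(qR) / (qR)]^2 circular cross-section form factor."""
    x = np.asarray(q, dtype=float) * R
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = (2.0 * special.j1(x[nz]) / x[nz]) ** 2
    return out


def reflection_weight(n, f):
    """Fourier weight of axial order n for a step density of duty cycle f."""
    n = np.asarray(n, dtype=float)
    return (np.sin(np.pi * n * f) / (np.pi * n)) ** 2


def collagen_profile(q_grid: np.ndarray, params: CollagenProfileParams,
                     n_orders: int | None = None) -> np.ndarray:
    """Model intensity I(q) on a strictly increasing positive q grid."""
    params.validate()
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size < 2 or np.any(np.diff(q) <= 0) or q[0] <= 0:
        raise ValueError("q grid must be 1D, positive and strictly increasing")
    if n_orders is None:
        # orders whose Gaussian tail could still touch the q range
        n_orders = int(np.ceil((q[-1] + 10.0 * params.peak_width)
                               * params.D / (2.0 * np.pi)))
    orders = np.arange(1, max(n_orders, 1) + 1)
    qn = 2.0 * np.pi * orders / params.D
    w = reflection_weight(orders, params.f)
    peaks = np.exp(-((q[:, None] - qn[None, :]) ** 2)
                   / (2.0 * params.peak_width ** 2)) @ w
    out = params.scale * _cylinder_factor(q, params.R) * peaks
    if params.a_hex is not None and params.hex_amp > 0:
        q_hex = 4.0 * np.pi / (params.a_hex * np.sqrt(3.0))
        out = out + params.hex_amp * np.exp(-((q - q_hex) ** 2)
                                            / (2.0 * params.peak_width ** 2))
    return out + params.background


@dataclass
class FibrilFitResult:
    params: CollagenProfileParams
    diameter_nm: float
    chi2_reduced: float
    converged: bool
    n_points: int


_FIT_FIELDS = ("D", "R", "f", "scale", "background", "peak_width")

DEFAULT_FIT_BOUNDS = {
    "D": (55.0, 75.0),
    "R": (20.0, 35.0),
    "f": (0.2, 0.8),
    "scale": (1e-12, np.inf),
    "background": (0.0, np.inf),
    "peak_width": (0.004, 0.08),
}


def fit_fibril_params(q: np.ndarray, intensity: np.ndarray,
                      init: CollagenProfileParams | None = None,
                      bounds: dict | None = None,
                      sigma: np.ndarray | None = None,
                      multi_start_R=(20.0, 25.0, 30.0),
                      ftol: float = 1e-8, max_nfev: int | None = None) -> FibrilFitResult:
    """Bounded least-squares fit of the profile model; diameter = 2R.

    Multi-start over initial radii, tie broken by the lowest chi^2.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if q.size < 30:
        raise ValueError("need at least 30 q points")
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensities")
    if init is None:
        init = CollagenProfileParams(scale=max(float(intensity.max()), 1e-9))
    b = dict(DEFAULT_FIT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[k][0] for k in _FIT_FIELDS])
    hi = np.array([b[k][1] for k in _FIT_FIELDS])
    w = 1.0 / np.asarray(sigma, dtype=float) if sigma is not None else 1.0

    def residual(x):
        p = replace(init, **dict(zip(_FIT_FIELDS, x)))
        return (collagen_profile(q, p) - intensity) * w

    best = None
    for r0 in multi_start_R:
        x0 = np.array([init.D, r0, init.f, init.scale, init.background,
                       init.peak_width])
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12 if np.all(np.isfinite(hi)) else x0)
        x0 = np.minimum(np.maximum(x0, lo), np.where(np.isfinite(hi), hi, x0))
        try:
            res = optimize.least_squares(residual, x0, bounds=(lo, hi),
                                         method="trf", x_scale="jac",
                                         ftol=ftol, xtol=ftol, gtol=ftol,
                                         max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")
    fitted = replace(init, **dict(zip(_FIT_FIELDS, best.x)))
    dof = max(q.size - len(_FIT_FIELDS), 1)
    chi2 = 2.0 * best.cost / dof
    converged = bool(best.status > 0 and np.isfinite(best.cost))
    return FibrilFitResult(params=fitted, diameter_nm=2.0 * fitted.R,
                           chi2_reduced=chi2, converged=converged,
                           n_points=int(q.size))


# ---------------------------------------------------------------------------
# Rank-2 tensor utilities

# component order for the packed symmetric representation
SYM6_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def matrix_to_sym6(A: np.ndarray) -> np.ndarray:
    """Pack (..., 3, 3) symmetric matrices into (..., 6) components."""
    A = np.asarray(A, dtype=float)
    return np.stack([A[..., i, j] for i, j in SYM6_IDX], axis=-1)


def sym6_to_matrix(s: np.ndarray) -> np.ndarray:
    """Unpack (..., 6) components into (..., 3, 3) symmetric matrices."""
    s = np.asarray(s, dtype=float)
    A = np.zeros(s.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(SYM6_IDX):
        A[..., i, j] = s[..., c]
        A[..., j, i] = s[..., c]
    return A


def probe_coefficients(u: np.ndarray) -> np.ndarray:
    """Coefficients c such that u^T A u = c . sym6(A), shape (..., 6)."""
    u = np.asarray(u, dtype=float)
    return np.stack([
        u[..., 0] ** 2, u[..., 1] ** 2, u[..., 2] ** 2,
        2.0 * u[..., 0] * u[..., 1],
        2.0 * u[..., 0] * u[..., 2],
        2.0 * u[..., 1] * u[..., 2],
    ], axis=-1)


def tensor_probe(A: np.ndarray, u: np.ndarray) -> float:
    """Quadratic form u^T A u for a symmetric 3x3 tensor."""
    A = np.asarray(A, dtype=float)
    u = np.asarray(u, dtype=float)
    return float(u @ A @ u)


def anisotropy_degree(A: np.ndarray, n_dirs: int = 10_000) -> float:
    """Directional coefficient of variation std/mean of u^T A u on the sphere.

    Directions come from a deterministic Fibonacci spiral, so the result is
    reproducible for a given ``n_dirs``.
    """
    dirs = fibonacci_sphere(n_dirs)
    vals = np.einsum("ni,ij,nj->n", dirs, np.asarray(A, dtype=float), dirs)
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("tensor has non-positive directional mean")
    return float(vals.std() / mean)


def anisotropy_degree_field(sym6: np.ndarray, n_dirs: int = 10_000,
                            chunk: int = 4096) -> np.ndarray:
    """Vectorised anisotropy degree for (n_vox, 6) packed tensors.

    Voxels with non-positive directional mean get NaN instead of raising.
    """
    coeff = probe_coefficients(fibonacci_sphere(n_dirs))  # (n_dirs, 6)
    sym6 = np.asarray(sym6, dtype=float)
    out = np.full(sym6.shape[0], np.nan)
    for start in range(0, sym6.shape[0], chunk):
        block = sym6[start:start + chunk]
        vals = block @ coeff.T  # (chunk, n_dirs)
        mean = vals.mean(axis=1)
        std = vals.std(axis=1)
        ok = mean > 0
        out[start:start + chunk][ok] = std[ok] / mean[ok]
    return out


# ---------------------------------------------------------------------------
# Azimuthal integration of 2D patterns


@dataclass
class SegmentedProfile:
    """Azimuthally segmented radial profile of a 2D pattern.

    ``intensity[seg, bin]`` is the mean count of pixels falling in that
    (segment, q) cell; empty cells are NaN with ``n_pixels`` 0.
    """

    q_centers: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray
    segment_edges_deg: np.ndarray = field(default=None)

    @property
    def total_counts(self) -> float:
        filled = self.n_pixels > 0
        return float(np.sum(self.intensity[filled] * self.n_pixels[filled]))

    def to_dataframe(self):
        """Long-format table: q_nm_inv, segment, intensity, sigma.

        sigma is the Poisson standard error of the per-cell mean; empty
        cells keep NaN intensity/sigma.
        """
        import pandas as pd

        n_seg, n_q = self.intensity.shape
        seg, qbin = np.meshgrid(np.arange(n_seg), np.arange(n_q),
                                indexing="ij")
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma = np.sqrt(self.intensity / np.maximum(self.n_pixels, 1))
        sigma = np.where(self.n_pixels > 0, sigma, np.nan)
        return pd.DataFrame({
            "q_nm_inv": self.q_centers[qbin.ravel()],
            "segment": seg.ravel(),
            "intensity": self.intensity.ravel(),
            "sigma": sigma.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def integrate_pattern_2d(image: np.ndarray, center: tuple[float, float],
                         pixel_size_mm: float, distance_mm: float,
                         beam: BeamSpec, n_segments: int,
                         q_edges: np.ndarray) -> SegmentedProfile:
    """Mean counts per (azimuthal segment, q bin) of a detector image.

    ``center`` is (row, col) in pixels.  Segment k spans azimuth
    [k, k+1) * 360/n degrees counter-clockwise from the detector +y
    (horizontal, column) axis; bin membership is by pixel centre.
    """
    image = np.asarray(image, dtype=float)
    q_edges = np.asarray(q_edges, dtype=float)
    if n_segments < 1:
        raise ValueError("need at least one azimuthal segment")
    if np.any(np.diff(q_edges) <= 0):
        raise ValueError("q edges must be strictly increasing")
    r0, c0 = center
    if not (0 <= r0 < image.shape[0] and 0 <= c0 < image.shape[1]):
        raise ValueError("beam centre outside image")

    rows, cols = np.indices(image.shape)
    dv = rows - r0          # vertical component
    dh = cols - c0          # horizontal (+y) component
    r_mm = np.hypot(dv, dh) * pixel_size_mm
    theta = np.arctan(r_mm / distance_mm)
    q = q_from_angle(theta.ravel(), beam.wavelength_nm).reshape(theta.shape)

    phi = np.mod(np.arctan2(dv, dh), 2.0 * np.pi)
    seg = np.minimum((phi / (2.0 * np.pi) * n_segments).astype(int),
                     n_segments - 1)
    qbin = np.searchsorted(q_edges, q, side="right") - 1
    valid = (qbin >= 0) & (qbin < q_edges.size - 1)

    n_q = q_edges.size - 1
    flat = seg[valid] * n_q + qbin[valid]
    counts = np.bincount(flat, minlength=n_segments * n_q).reshape(n_segments, n_q)
    sums = np.bincount(flat, weights=image[valid],
                       minlength=n_segments * n_q).reshape(n_segments, n_q)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges_deg = np.arange(n_segments + 1) * 360.0 / n_segments
    return SegmentedProfile(q_centers=0.5 * (q_edges[:-1] + q_edges[1:]),
                            intensity=mean, n_pixels=counts,
                            segment_edges_deg=edges_deg)
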