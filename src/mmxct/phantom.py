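"""Seeded synthetic specimens with controllable field-to-field coupling.

A cylindrical support holds smooth random fields for collagen density,
orientation (unit vectors), degree of anisotropy, fibril diameter, Fe/Zn
concentration and linear attenuation.  The four analysis scalars
(anisotropy, diameter, Fe, Zn) are coupled through a Gaussian copula on
shared smooth latent fields so their pairwise Pearson correlations can be
dialled in and later recovered by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "AlignedRegion",
    "Hotspot",
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "phantom_ground_truth_maps",
    "coupling_matrix",
    "sample_vmf",
]

COUPLED_FIELDS = ("anisotropy", "diameter", "fe", "zn")


@dataclass(frozen=True)
class AlignedRegion:
    """Spherical region (fractional grid coordinates) of oriented collagen."""

    center_frac: tuple[float, float, float] = (0.5, 0.5, 0.68)
    radius_frac: float = 0.22
    target_anisotropy: float = 0.9
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class Hotspot:
    """Gaussian concentration bump; by default co-located with the aligned region."""

    center_frac: tuple[float, float, float] | None = None
    radius_frac: float = 0.18
    fe_amp: float = 1.0
    zn_amp: float = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 32, 40)
    voxel_size_mm: float = 0.0375
    cylinder_diameter_mm: float = 1.2
    cylinder_height_mm: float | None = None  # None: full grid height
    aligned_region: AlignedRegion | None = AlignedRegion()
    hotspot: Hotspot | None = Hotspot()
    diameter_range_nm: tuple[float, float] = (46.0, 54.0)
    # target Pearson correlations between the coupled scalar fields
    coupling: dict = field(default_factory=lambda: {
        ("anisotropy", "diameter"): 0.81,
        ("anisotropy", "fe"): 0.77,
        ("anisotropy", "zn"): 0.88,
        ("diameter", "fe"): 0.70,
        ("diameter", "zn"): 0.84,
        ("fe", "zn"): 0.89,
    })
    texture_voxels: float = 1.5
    # smooth radial taper (voxels) of density/metal/mu towards the support
    # edge; 0 keeps a hard edge (which rings under filtered back-projection)
    edge_taper_voxels: float = 0.0
    anisotropy_mean: float = 0.45
    anisotropy_std: float = 0.15
    anisotropy_limits: tuple[float, float] = (0.02, 0.95)
    fe_level: float = 1.0
    zn_level: float = 1.0
    conc_cv: float = 0.25
    density_level: float = 1.0
    density_cv: float = 0.2
    mu_mm_inv: float = 0.2
    mu_texture: float = 0.2
    axial_period_nm: float = 65.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.diameter_range_nm
        if not (40.0 <= lo < hi <= 70.0):
            raise ValueError("diameter range must lie within [40, 70] nm")
        for pair, rho in self.coupling.items():
            if not (-1.0 < rho < 1.0):
                raise ValueError(f"coupling rho for {pair} outside (-1, 1)")
        coupling_matrix(self.coupling)  # raises if not PSD


def coupling_matrix(coupling: dict) -> np.ndarray:
    """Unit-diagonal 4x4 correlation matrix over the coupled fields.

    Raises ValueError when the completed matrix is not symmetric positive
    semidefinite.
    """
    n = len(COUPLED_FIELDS)
    C = np.eye(n)
    index = {name: i for i, name in enumerate(COUPLED_FIELDS)}
    for (a, b), rho in coupling.items():
        if a not in index or b not in index:
            raise ValueError(f"unknown coupled field pair ({a}, {b})")
        C[index[a], index[b]] = rho
        C[index[b], index[a]] = rho
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10:
        raise ValueError(
            "coupling matrix is not positive semidefinite after unit-diagonal "
            f"completion (min eigenvalue {eigvals.min():.3g}); "
            "reduce the requested correlations")
    return C


@dataclass
class Phantom:
    """Voxelised ground truth; all fields zero outside the support cylinder."""

    voxel_size_mm: float
    collagen_density: np.ndarray
    orientation: np.ndarray       # (nx, ny, nz, 3) unit vectors in support
    anisotropy: np.ndarray
    fibril_diameter: np.ndarray   # nm
    fe_conc: np.ndarray
    zn_conc: np.ndarray
    mu: np.ndarray                # mm^-1 at beam energy
    support_mask: np.ndarray
    axial_period_nm: float = 65.0
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.collagen_density.shape

    def scalar_fields(self) -> dict[str, np.ndarray]:
        return {"anisotropy": self.anisotropy,
                "diameter": self.fibril_diameter,
                "fe": self.fe_conc, "zn": self.zn_conc}


def _smooth_standard_normal(rng, shape, sigma_vox):
    """Smooth random field, re-standardised to zero mean / unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox,
                                mode="nearest")
    return (f - f.mean()) / f.std()


def sample_vmf(axis: np.ndarray, kappa: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw n unit vectors from a von Mises-Fisher distribution on S2."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if kappa < 1e-9:
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    # inverse-CDF sampling of cos(angle) for vMF on the 2-sphere
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.random(n) * 2.0 * np.pi
    s = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    # rotate local +z onto the requested axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ R.T


def _region_mask(shape, center_frac, radius_frac):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    d2 = sum(((g / (s - 1) - c) * s) ** 2
             for g, s, c in zip(grids, shape, center_frac))
    radius = radius_frac * max(shape)
    return d2 <= radius ** 2, np.sqrt(d2), radius


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> Phantom:
    """Generate a seeded phantom satisfying the type invariants."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    shape = config.shape
    nx, ny, nz = shape

    # cylindrical support along z
    xi = (np.arange(nx) - (nx - 1) / 2.0) * config.voxel_size_mm
    yi = (np.arange(ny) - (ny - 1) / 2.0) * config.voxel_size_mm
    zi = (np.arange(nz) - (nz - 1) / 2.0) * config.voxel_size_mm
    X, Y, Z = np.meshgrid(xi, yi, zi, indexing="ij")
    radius = config.cylinder_diameter_mm / 2.0
    r_mm = np.sqrt(X ** 2 + Y ** 2)
    support = r_mm <= radius
    if config.cylinder_height_mm is not None:
        support &= np.abs(Z) <= config.cylinder_height_mm / 2.0
    if config.edge_taper_voxels > 0:
        t = np.clip((radius - r_mm)
                    / (config.edge_taper_voxels * config.voxel_size_mm), 0.0, 1.0)
        taper = t * t * (3.0 - 2.0 * t)      # smoothstep
    else:
        taper = 1.0

    # coupled latent fields: independent smooth gaussians mixed by Cholesky
    C = coupling_matrix(config.coupling)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(4))
    base = np.stack([_smooth_standard_normal(rng, shape, config.texture_voxels)
                     for _ in range(4)])
    latent = np.einsum("ij,j...->i...", L, base)
    z_an, z_di, z_fe, z_zn = latent

    a_lo, a_hi = config.anisotropy_limits
    anisotropy = np.clip(config.anisotropy_mean
                         + config.anisotropy_std * z_an, a_lo, a_hi)
    d_lo, d_hi = config.diameter_range_nm
    d_mid, d_half = 0.5 * (d_lo + d_hi), 0.5 * (d_hi - d_lo)
    # 3.2 sigma inside the half-range keeps clipping rare (affine elsewhere)
    diameter = np.clip(d_mid + (d_half / 3.2) * z_di, d_lo, d_hi)
    fe = config.fe_level * np.maximum(1.0 + config.conc_cv * z_fe, 0.0)
    zn = config.zn_level * np.maximum(1.0 + config.conc_cv * z_zn, 0.0)

    # aligned region: anisotropy floor + oriented axis; hotspots add metal
    orientation = sample_vmf(np.array([0.0, 0.0, 1.0]), 0.0, int(np.prod(shape)),
                             rng).reshape(shape + (3,))
    if config.aligned_region is not None:
        reg = config.aligned_region
        mask, _, _ = _region_mask(shape, reg.center_frac, reg.radius_frac)
        anisotropy[mask] = np.maximum(anisotropy[mask], reg.target_anisotropy)
        a = reg.target_anisotropy
        kappa = 2.0 * a / max((1.0 - a) ** 2, 1e-6)
        orientation[mask] = sample_vmf(np.asarray(reg.axis, dtype=float),
                                       kappa, int(mask.sum()), rng)
    if config.hotspot is not None and (config.hotspot.fe_amp > 0
                                       or config.hotspot.zn_amp > 0):
        hs = config.hotspot
        center = hs.center_frac
        if center is None and config.aligned_region is not None:
            center = config.aligned_region.center_frac
        if center is None:
            center = (0.5, 0.5, 0.5)
        _, dist, radius = _region_mask(shape, center, hs.radius_frac)
        bump = np.exp(-0.5 * (dist / max(radius, 1e-9)) ** 2)
        fe = fe + hs.fe_amp * config.fe_level * bump
        zn = zn + hs.zn_amp * config.zn_level * bump

    density = config.density_level * np.maximum(
        1.0 + config.density_cv
        * _smooth_standard_normal(rng, shape, config.texture_voxels), 0.05)
    mu = config.mu_mm_inv * (1.0 + config.mu_texture
                             * _smooth_standard_normal(rng, shape,
                                                       config.texture_voxels))
    mu = np.maximum(mu, 0.0)

    out = Phantom(
        voxel_size_mm=config.voxel_size_mm,
        collagen_density=np.where(support, density * taper, 0.0),
        orientation=np.where(support[..., None], orientation, 0.0),
        anisotropy=np.where(support, anisotropy, 0.0),
        fibril_diameter=np.where(support, diameter, 0.0),
        fe_conc=np.where(support, fe * taper, 0.0),
        zn_conc=np.where(support, zn * taper, 0.0),
        mu=np.where(support, mu * taper, 0.0),
        support_mask=support,
        axial_period_nm=config.axial_period_nm,
        seed=seed,
    )
    return out


def phantom_ground_truth_maps(phantom: Phantom, roi=None) -> dict:
    """Support-masked ground-truth maps restricted to an ROI box.

    ``roi`` is ((x0, x1), (y0, y1), (z0, z1)) half-open voxel bounds; None
    takes the full grid.  Returns a dict of (values, mask) pairs for the four
    coupled scalars.
    """
    if roi is None:
        roi = tuple((0, s) for s in phantom.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in roi)
    for (a, b), s in zip(roi, phantom.shape):
        if not (0 <= a < b <= s):
            raise ValueError(f"empty or out-of-range roi bound ({a}, {b})")
    mask = phantom.support_mask[sl]
    out = {}
    for name, vals in phantom.scalar_fields().items():
        out[name] = (np.where(mask, vals[sl], 0.0), mask.copy())
    return out
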