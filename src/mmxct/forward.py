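"""Scanning-acquisition simulators: transmission, azimuthally segmented
SAXS sinograms over rotations and tilts, and energy-dispersive XRF spectra
with optional self-absorption.

All simulators are deterministic given (phantom, geometry, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geom import JosephProjector, lab_to_sample_matrix
from .phantom import Phantom
from .scatter_model import BeamSpec, probe_coefficients, reflection_weight
from .recon import _segment_directions

__all__ = [
    "EmissionLine",
    "DEFAULT_LINE_TABLE",
    "Frame",
    "ScanGeometry",
    "AzimuthalSinogram",
    "XRFScan",
    "count_acquired",
    "simulate_transmission",
    "simulate_saxs_scan",
    "simulate_xrf_scan",
    "simulate_reference_spectrum",
]


@dataclass(frozen=True)
class EmissionLine:
    element: str
    line: str
    energy_kev: float
    rel_intensity: float


# K-alpha/K-beta energies with the beta/alpha branching ratio folded in
DEFAULT_LINE_TABLE = (
    EmissionLine("Fe", "Ka", 6.404, 1.0),
    EmissionLine("Fe", "Kb", 7.058, 0.135),
    EmissionLine("Zn", "Ka", 8.639, 1.0),
    EmissionLine("Zn", "Kb", 9.572, 0.135),
)


@dataclass(frozen=True)
class Frame:
    """One projection: a tilt/rotation pair with its raster offsets."""

    tilt_deg: float
    rotation_deg: float
    y_offsets_mm: np.ndarray
    z_offsets_mm: np.ndarray

    @property
    def n_rays(self) -> int:
        return self.y_offsets_mm.size * self.z_offsets_mm.size


def _default_rotations():
    return ((0.0, np.arange(0.0, 180.0, 180.0 / 12)),
            (27.0, np.arange(0.0, 360.0, 360.0 / 12)),
            (45.0, np.arange(0.0, 360.0, 360.0 / 12)))


@dataclass(frozen=True)
class ScanGeometry:
    """Raster + rotation/tilt schedule and beam/detector parameters."""

    n_y: int = 32
    n_z: int = 40
    step_mm: float = 0.0375
    schedule: tuple = field(default_factory=_default_rotations)
    beam: BeamSpec = field(default_factory=BeamSpec)
    detector_distance_m: float = 5.08
    n_segments: int = 16
    exposure_s: float = 0.1
    flux: float = 1e6
    counts_per_unit: float = 1.0
    tilt_pad: int = 6  # extra raster steps per side for tilted projections
    q_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 2.15, 37))

    def __post_init__(self):
        tilts = [t for t, _ in self.schedule]
        if 0.0 not in tilts:
            raise ValueError("tilt schedule must include 0 degrees")
        if self.step_mm <= 0:
            raise ValueError("step size must be positive")
        for _, rots in self.schedule:
            r = np.asarray(rots, dtype=float)
            if np.any(r < 0) or np.any(r >= 360.0):
                raise ValueError("rotations must lie in [0, 360)")

    def grid_shape(self, tilt_deg: float) -> tuple[int, int]:
        if tilt_deg == 0.0:
            return self.n_y, self.n_z
        return self.n_y + 2 * self.tilt_pad, self.n_z + 2 * self.tilt_pad

    def _offsets(self, tilt_deg: float):
        ny, nz = self.grid_shape(tilt_deg)
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.step_mm
        z = (np.arange(nz) - (nz - 1) / 2.0) * self.step_mm
        return y, z

    def frames(self) -> list[Frame]:
        out = []
        for tilt, rots in self.schedule:
            y, z = self._offsets(tilt)
            for rot in np.asarray(rots, dtype=float):
                out.append(Frame(float(tilt), float(rot), y, z))
        return out

    def tilt0_rotations(self) -> np.ndarray:
        for tilt, rots in self.schedule:
            if tilt == 0.0:
                return np.asarray(rots, dtype=float)
        raise ValueError("no tilt-0 schedule")


def count_acquired(geometry: ScanGeometry, modality: str) -> int:
    """Number of recorded patterns/spectra for the given modality.

    XRF spectra are recorded only at the upright (tilt 0) rotations; SAXS
    patterns at every raster point of every projection.
    """
    if modality == "xrf":
        return int(geometry.tilt0_rotations().size * geometry.n_y * geometry.n_z)
    if modality == "saxs":
        total = 0
        for tilt, rots in geometry.schedule:
            ny, nz = geometry.grid_shape(tilt)
            total += int(np.asarray(rots).size * ny * nz)
        return total
    raise ValueError(f"unknown modality {modality!r}")


@dataclass
class AzimuthalSinogram:
    """Per-frame segmented SAXS intensities plus the transmission sinogram."""

    frames: list
    intensities: list          # per frame (n_y, n_z, n_segments, n_q)
    transmission: list         # per frame (n_y, n_z)
    q_edges: np.ndarray
    step_mm: float
    exposure_s: float
    flux: float
    counts_per_unit: float
    q5_index: int

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])


def simulate_transmission(phantom: Phantom, geometry: ScanGeometry,
                          step_frac: float = 0.5) -> list:
    """Noiseless Beer-Lambert transmission per frame, each (n_y, n_z)."""
    projector = JosephProjector(phantom.shape, phantom.voxel_size_mm,
                                step_frac=step_frac)
    mu_flat = phantom.mu.ravel()
    out = []
    for fr in geometry.frames():
        S = projector.ray_matrix(fr.tilt_deg, fr.rotation_deg,
                                 fr.y_offsets_mm, fr.z_offsets_mm)
        integral = (S @ mu_flat).reshape(fr.y_offsets_mm.size,
                                         fr.z_offsets_mm.size)
        out.append(np.exp(-integral))
    return out


def _voxel_tensors(phantom: Phantom) -> np.ndarray:
    """Packed per-voxel tensors density * ((1-a)/3 I + a e e^T), (n_vox, 6)."""
    rho = phantom.collagen_density.ravel()
    a = phantom.anisotropy.ravel()
    e = phantom.orientation.reshape(-1, 3)
    t6 = np.empty((rho.size, 6))
    iso = rho * (1.0 - a) / 3.0
    t6[:, 0] = iso + rho * a * e[:, 0] ** 2
    t6[:, 1] = iso + rho * a * e[:, 1] ** 2
    t6[:, 2] = iso + rho * a * e[:, 2] ** 2
    t6[:, 3] = rho * a * e[:, 0] * e[:, 1]
    t6[:, 4] = rho * a * e[:, 0] * e[:, 2]
    t6[:, 5] = rho * a * e[:, 1] * e[:, 2]
    return t6


def _profile_shape(phantom: Phantom, q_centers: np.ndarray, q5: float,
                   profile_f: float = 0.53,
                   peak_width: float = 0.02) -> np.ndarray:
    """Per-voxel I(q)/I(q5) profile shape, (n_vox, n_q), finite everywhere."""
    from scipy import special

    D = phantom.axial_period_nm
    n_orders = int(np.ceil((q_centers[-1] + 10 * peak_width) * D / (2 * np.pi)))
    orders = np.arange(1, n_orders + 1)
    qn = 2.0 * np.pi * orders / D
    w = reflection_weight(orders, profile_f)

    def peaks(q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        return np.exp(-((q[:, None] - qn[None, :]) ** 2)
                      / (2.0 * peak_width ** 2)) @ w

    R = np.maximum(phantom.fibril_diameter.ravel() / 2.0, 1.0)

    def cyl(q):
        x = np.outer(R, np.atleast_1d(q))
        return (2.0 * special.j1(x) / x) ** 2

    pk = peaks(q_centers)
    pk5 = peaks(q5)[0]
    num = cyl(q_centers) * pk[None, :]
    den = np.maximum(cyl(q5)[:, 0] * pk5, 1e-300)
    return num / den[:, None]


def q5_index(q_edges: np.ndarray, axial_period_nm: float) -> int:
    """Index of the q bin containing the 5th-order axial reflection."""
    q5 = 2.0 * np.pi * 5.0 / axial_period_nm
    idx = int(np.searchsorted(q_edges, q5, side="right") - 1)
    if not (0 <= idx < q_edges.size - 1):
        raise ValueError("5th-order reflection outside the q range")
    return idx


def simulate_saxs_scan(phantom: Phantom, geometry: ScanGeometry,
                       seed: int | None = 0, noise: bool = True,
                       profile_f: float = 0.53,
                       peak_width: float = 0.02) -> AzimuthalSinogram:
    """Segmented SAXS sinogram over all frames of the geometry.

    The measured intensity in segment phi at q bin b is the beam-path line
    integral of ``u^T A(v) u * shape_v(q_b)`` attenuated by the sample
    transmission, scaled to counts by exposure * flux * counts_per_unit, with
    optional Poisson noise.
    """
    q_edges = np.asarray(geometry.q_edges, dtype=float)
    q_centers = 0.5 * (q_edges[:-1] + q_edges[1:])
    i5 = q5_index(q_edges, phantom.axial_period_nm)
    q5 = 2.0 * np.pi * 5.0 / phantom.axial_period_nm

    t6 = _voxel_tensors(phantom)
    shape = _profile_shape(phantom, q_centers, q5, profile_f, peak_width)
    projector = JosephProjector(phantom.shape, phantom.voxel_size_mm)
    trans = simulate_transmission(phantom, geometry)
    rng = np.random.default_rng(seed)
    scale = geometry.exposure_s * geometry.flux * geometry.counts_per_unit

    frames = geometry.frames()
    intensities = []
    for fr, T in zip(frames, trans):
        S = projector.ray_matrix(fr.tilt_deg, fr.rotation_deg,
                                 fr.y_offsets_mm, fr.z_offsets_mm)
        dirs = _segment_directions(geometry.n_segments, fr.tilt_deg,
                                   fr.rotation_deg)
        probe = t6 @ probe_coefficients(dirs).T     # (n_vox, n_seg)
        out = np.empty((fr.y_offsets_mm.size, fr.z_offsets_mm.size,
                        geometry.n_segments, q_centers.size), dtype=np.float64)
        for s in range(geometry.n_segments):
            proj = S @ (probe[:, s:s + 1] * shape)  # (n_rays, n_q)
            out[:, :, s, :] = proj.reshape(out.shape[0], out.shape[1], -1)
        expected = out * T[:, :, None, None] * scale
        if noise:
            expected = rng.poisson(np.maximum(expected, 0.0)).astype(np.float64)
        intensities.append(expected.astype(np.float32))
    return AzimuthalSinogram(frames=frames, intensities=intensities,
                             transmission=trans, q_edges=q_edges,
                             step_mm=geometry.step_mm,
                             exposure_s=geometry.exposure_s, flux=geometry.flux,
                             counts_per_unit=geometry.counts_per_unit,
                             q5_index=i5)


# ---------------------------------------------------------------------------
# XRF


@dataclass
class XRFScan:
    """Energy-dispersive spectra at the tilt-0 rotations."""

    counts: np.ndarray          # (n_rot, n_y, n_z, n_channels)
    rotations_deg: np.ndarray
    gain_kev: float             # true calibration, recoverable from reference
    offset_kev: float
    line_table: tuple
    detector_sigma_kev: float
    exposure_s: float
    flux: float
    # noiseless per-element path integrals (mm units), for oracle tests
    true_line_integrals: dict | None = None

    @property
    def n_channels(self) -> int:
        return self.counts.shape[-1]

    def energies(self) -> np.ndarray:
        return self.offset_kev + self.gain_kev * np.arange(self.n_channels)


def _lab_grid_samples(volume: np.ndarray, voxel_size_mm: float,
                     rot_deg: float, x_mm: np.ndarray, y_mm: np.ndarray,
                     z_mm: np.ndarray) -> np.ndarray:
    """Sample a specimen volume on a regular lab-frame grid (tilt 0)."""
    M = lab_to_sample_matrix(0.0, rot_deg)
    X, Y, Z = np.meshgrid(x_mm, y_mm, z_mm, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) @ M.T
    half = (np.array(volume.shape) - 1.0) / 2.0
    idx = pts / voxel_size_mm + half
    return ndimage.map_coordinates(volume, idx.reshape(-1, 3).T, order=1,
                                   cval=0.0).reshape(X.shape)


def simulate_xrf_scan(phantom: Phantom, geometry: ScanGeometry,
                      absorption: bool = True, seed: int | None = 0,
                      noise: bool = True, n_channels: int = 1024,
                      gain_kev: float = 0.011, offset_kev: float = 0.0,
                      detector_sigma_kev: float = 0.08,
                      line_table: tuple = DEFAULT_LINE_TABLE,
                      counts_per_unit: float = 1e-2,
                      background_rate: float = 0.05) -> XRFScan:
    """XRF spectra with Beer-Lambert self-absorption.

    The fluorescence detector sits at 90 degrees in the horizontal plane
    (lab +y); the exit-path attenuation coefficient is the beam-energy mu
    scaled by (E_beam / E_line)^3.  ``absorption=False`` disables both the
    incident and exit attenuation.
    """
    rotations = geometry.tilt0_rotations()
    rng = np.random.default_rng(seed)
    vox = phantom.voxel_size_mm
    conc = {"Fe": phantom.fe_conc, "Zn": phantom.zn_conc}

    # lab-frame grid: fine steps along the beam, raster steps across
    extent = 0.5 * float(np.linalg.norm(np.array(phantom.shape))) * vox
    dx = vox / 2.0
    x_mm = np.arange(-extent, extent + dx, dx)
    y_mm, z_mm = geometry._offsets(0.0)
    dy = geometry.step_mm
    e_beam = geometry.beam.energy_kev

    energies = offset_kev + gain_kev * np.arange(n_channels)
    counts = np.empty((rotations.size, y_mm.size, z_mm.size, n_channels),
                      dtype=np.float64)
    elements = sorted(conc)
    true_integrals = {el: np.empty((rotations.size, y_mm.size, z_mm.size))
                      for el in elements}
    projector = None
    if not absorption:
        # plain line integrals: share the Joseph ray tracer with the rest of
        # the pipeline so oracle comparisons are exact
        projector = JosephProjector(phantom.shape, vox)
    for ir, rot in enumerate(rotations):
        paths = {}
        if absorption:
            mu = _lab_grid_samples(phantom.mu, vox, rot, x_mm, y_mm, z_mm)
            cum_in = np.cumsum(mu, axis=0) * dx - mu * dx / 2.0
            t_in = np.exp(-cum_in)
            # integral of mu from each point to the +y edge (detector side)
            rev = np.flip(np.cumsum(np.flip(mu, axis=1), axis=1), axis=1)
            exit_integral = rev * dy - mu * dy / 2.0
        else:
            S = projector.ray_matrix(0.0, rot, y_mm, z_mm)
            for el in elements:
                paths[el] = (S @ conc[el].ravel()).reshape(y_mm.size, z_mm.size)
        spectra = np.full((y_mm.size, z_mm.size, n_channels),
                          background_rate * geometry.exposure_s)
        for ln in line_table:
            if absorption:
                c = _lab_grid_samples(conc[ln.element], vox, rot,
                                      x_mm, y_mm, z_mm)
                s_line = (e_beam / ln.energy_kev) ** 3
                t_out = np.exp(-s_line * exit_integral)
                path = (c * t_in * t_out).sum(axis=0) * dx
            else:
                path = paths[ln.element]
            if ln.line == "Ka":
                true_integrals[ln.element][ir] = path
            area = (path * geometry.exposure_s * geometry.flux
                    * counts_per_unit * ln.rel_intensity)
            profile = (np.exp(-((energies - ln.energy_kev) ** 2)
                              / (2.0 * detector_sigma_kev ** 2))
                       * gain_kev / (detector_sigma_kev * np.sqrt(2 * np.pi)))
            spectra += area[:, :, None] * profile[None, None, :]
        counts[ir] = spectra
    if noise:
        counts = rng.poisson(np.maximum(counts, 0.0)).astype(np.float64)
    return XRFScan(counts=counts, rotations_deg=rotations,
                   gain_kev=gain_kev, offset_kev=offset_kev,
                   line_table=line_table,
                   detector_sigma_kev=detector_sigma_kev,
                   exposure_s=geometry.exposure_s, flux=geometry.flux,
                   true_line_integrals=true_integrals)


def simulate_reference_spectrum(known_lines_kev, gain_kev: float = 0.011,
                                offset_kev: float = 0.0,
                                n_channels: int = 1024,
                                detector_sigma_kev: float = 0.08,
                                peak_counts: float = 1e5,
                                background: float = 10.0,
                                seed: int | None = None) -> np.ndarray:
    """Calibration-standard spectrum with peaks at the known line energies."""
    energies = offset_kev + gain_kev * np.arange(n_channels)
    spec = np.full(n_channels, background)
    for e in known_lines_kev:
        spec += peak_counts * np.exp(-((energies - e) ** 2)
                                     / (2.0 * detector_sigma_kev ** 2))
    if seed is not None:
        spec = np.random.default_rng(seed).poisson(spec).astype(float)
    return spec
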