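"""Results-level computations: reverse analysis to per-voxel profiles,
fibril-diameter mapping, low-collagen masking, 0-255 normalisation and the
pairwise cross-correlation table."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recon import ScalarVolume
from .scatter_model import CollagenProfileParams, fit_fibril_params

__all__ = [
    "CorrelationTable",
    "reverse_profiles",
    "diameter_map",
    "mask_low_collagen",
    "normalize_0_255",
    "correlation_table",
]

TABLE_LABELS = ("collagen_orientation", "collagen_diameter", "fe", "zn")


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations of the four analysis maps."""

    matrix: np.ndarray
    labels: tuple
    n_voxels: int
    mask_provenance: str = ""
    degenerate: tuple = ()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.6f")

    def __getitem__(self, pair):
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.matrix[i, j])


def reverse_profiles(q_volumes: np.ndarray, q_centers: np.ndarray,
                     roi, mask: np.ndarray):
    """Per-voxel SAXS profiles from q-resolved reconstructions.

    ``q_volumes`` is (n_q, nx, ny, nz) on a common grid; ``roi`` is
    ((x0, x1), (y0, y1), (z0, z1)) half-open voxel bounds.  Returns
    (q_centers, profiles, voxel_indices) with profiles shaped
    (n_unmasked, n_q) and voxel_indices the (n_unmasked, 3) grid positions.
    """
    q_volumes = np.asarray(q_volumes, dtype=float)
    sl = tuple(slice(int(a), int(b)) for a, b in roi)
    grid_shape = q_volumes.shape[1:]
    for (a, b), s in zip(roi, grid_shape):
        if not (0 <= a < b <= s):
            raise ValueError(f"empty or out-of-range roi bound ({a}, {b})")
    sub_mask = np.asarray(mask, dtype=bool)[sl]
    if not sub_mask.any():
        raise ValueError("roi contains no unmasked voxels")
    sub = q_volumes[(slice(None),) + sl]
    profiles = sub[:, sub_mask].T                  # (n_vox, n_q)
    idx = np.argwhere(sub_mask) + np.array([a for a, _ in roi])
    return np.asarray(q_centers, dtype=float), profiles, idx


def diameter_map(q_centers: np.ndarray, profiles: np.ndarray,
                 voxel_indices: np.ndarray, grid_shape, voxel_size_mm: float,
                 init: CollagenProfileParams | None = None,
                 bounds: dict | None = None, **fit_kwargs) -> ScalarVolume:
    """Per-voxel fibril-diameter (2R, nm) map from reverse-analysis profiles.

    Non-converged voxels are masked out rather than reported.  Extra keyword
    arguments are passed through to ``fit_fibril_params`` (e.g. ``ftol``,
    ``multi_start_R`` to trade accuracy for speed on large ROIs).
    """
    values = np.zeros(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    for prof, (i, j, k) in zip(profiles, voxel_indices):
        try:
            fit = fit_fibril_params(q_centers, prof, init=init, bounds=bounds,
                                    **fit_kwargs)
        except (ValueError, RuntimeError):
            continue
        if fit.converged:
            values[i, j, k] = fit.diameter_nm
            mask[i, j, k] = True
    return ScalarVolume(values=values, voxel_size_mm=voxel_size_mm,
                        label="fibril-diameter", mask=mask)


def mask_low_collagen(mean_scattering: ScalarVolume, fraction: float = 0.10,
                      erode: int = 0) -> np.ndarray:
    """Keep voxels whose value reaches ``fraction`` of the in-support max.

    ``erode`` additionally peels that many voxel layers off the support
    boundary, where filtered back-projection ringing concentrates.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    vals = mean_scattering.values
    support = mean_scattering.mask
    if erode > 0:
        from scipy import ndimage
        support = ndimage.binary_erosion(support, iterations=erode)
    vmax = vals[support].max() if support.any() else vals.max()
    return support & (vals >= fraction * vmax)


def normalize_0_255(volume: ScalarVolume, mask: np.ndarray) -> ScalarVolume:
    """Affine rescale of the unmasked values so min -> 0 and max -> 255.

    Values stay floating point (no integer rounding); masked voxels are 0.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = volume.values[mask]
    if vals.size < 2:
        raise ValueError("need at least two unmasked voxels")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise ValueError("constant map: 0-255 normalisation undefined")
    out = np.zeros_like(volume.values)
    out[mask] = (volume.values[mask] - lo) * (255.0 / (hi - lo))
    return ScalarVolume(values=out, voxel_size_mm=volume.voxel_size_mm,
                        label=volume.label + "-norm255", mask=mask)


def correlation_table(orientation_degree: ScalarVolume,
                      diameter: ScalarVolume, fe: ScalarVolume,
                      zn: ScalarVolume, mask: np.ndarray,
                      mask_provenance: str = "") -> CorrelationTable:
    """Voxel-wise Pearson correlations over the common masked ROI."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 10:
        raise ValueError("need at least 10 unmasked voxels")
    stack = [vol.values[mask] for vol in
             (orientation_degree, diameter, fe, zn)]
    degenerate = tuple(TABLE_LABELS[i] for i, v in enumerate(stack)
                       if np.std(v) == 0)
    matrix = np.full((4, 4), np.nan)
    for i in range(4):
        for j in range(i, 4):
            if TABLE_LABELS[i] in degenerate or TABLE_LABELS[j] in degenerate:
                continue
            if i == j:
                matrix[i, j] = 1.0
            else:
                r = float(np.corrcoef(stack[i], stack[j])[0, 1])
                matrix[i, j] = matrix[j, i] = r
    return CorrelationTable(matrix=matrix, labels=TABLE_LABELS, n_voxels=n,
                            mask_provenance=mask_provenance,
                            degenerate=degenerate)
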