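"""Functional connectivity strength: a weighted degree-centrality map.

For each in-mask voxel i,

    FCS(i) = sum_{j != i, in mask} atanh(r_ij) * 1[r_ij > r_threshold]

where r_ij is the Pearson correlation between the preprocessed series of
voxels i and j and atanh is the Fisher r-to-z transform. With
``scale='mean'`` the sum is divided by (n_mask - 1) so values are
comparable across mask sizes. Correlations are clipped to
+/-(1 - 1e-7) before atanh; the positive threshold (default r > 0.1,
strict) excludes weak and negative correlations. The correlation matrix
is processed in row blocks, so the full V x V matrix is never held for
large masks.
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import numpy as np
from scipy import ndimage

from .types import BoldRun, FcsMap

R_CLIP = 1.0 - 1e-7
DEFAULT_R_THRESHOLD = 0.1
DEFAULT_FWHM_MM = 4.0
_BLOCK = 2048


def compute_fcs(
    run: BoldRun,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    scale: str = "mean",
    block_size: int = _BLOCK,
) -> FcsMap:
    """Voxel-wise FCS of a preprocessed run.

    Zero-variance voxels get FCS = 0, are counted in
    ``FcsMap.n_zero_variance``, and contribute no correlation terms.
    """
    if scale not in ("sum", "mean"):
        raise ValueError(f"scale must be 'sum' or 'mean', got {scale!r}")
    y = run.data[run.mask]  # V x t
    n_vox = y.shape[0]
    if n_vox < 2:
        raise ValueError("need at least 2 in-mask voxels")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values inside the mask")
    constant = np.ptp(y, axis=1) == 0  # exact-constant series
    y = y - y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(y, axis=1)
    zero_var = constant | (norms == 0)
    n_zero = int(zero_var.sum())
    if n_vox - n_zero < 2:
        raise ValueError("fewer than 2 in-mask voxels with temporal variance")
    z = np.zeros_like(y)
    z[~zero_var] = y[~zero_var] / norms[~zero_var, None]

    fcs = np.zeros(n_vox)
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        r = z[start:stop] @ z.T  # block x V
        np.clip(r, -R_CLIP, R_CLIP, out=r)
        # the diagonal of the full matrix never passes (self-correlation)
        r[np.arange(start, stop) - start, np.arange(start, stop)] = 0.0
        zmat = np.where(r > r_threshold, np.arctanh(r), 0.0)
        fcs[start:stop] = zmat.sum(axis=1)
    fcs[zero_var] = 0.0
    if scale == "mean":
        fcs = fcs / (n_vox - 1)

    out = np.zeros(run.spatial_shape)
    out[run.mask] = fcs
    return FcsMap(
        data=out,
        mask=run.mask,
        r_threshold=r_threshold,
        scale=scale,
        voxel_size_mm=tuple(run.voxel_size_mm),
        affine=run.affine,
        n_zero_variance=n_zero,
    )


def gaussian_smooth(fcs_map: FcsMap, fwhm_mm: float = DEFAULT_FWHM_MM) -> FcsMap:
    """Mask-restricted Gaussian smoothing with boundary renormalization.

    sigma per axis is fwhm_mm / (voxel_size_axis * sqrt(8 ln 2)). The map
    is convolved inside the mask and divided by the smoothed mask, so
    out-of-mask zeros do not bleed in and a constant map stays constant.
    fwhm_mm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return fcs_map
    sigma = [
        fwhm_mm / (vs * np.sqrt(8.0 * np.log(2.0)))
        for vs in fcs_map.voxel_size_mm
    ]
    masked = np.where(fcs_map.mask, fcs_map.data, 0.0)
    num = ndimage.gaussian_filter(masked, sigma=sigma, mode="constant")
    den = ndimage.gaussian_filter(
        fcs_map.mask.astype(np.float64), sigma=sigma, mode="constant"
    )
    out = np.zeros_like(num)
    inside = fcs_map.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return dataclasses.replace(fcs_map, data=out)


def extract_cluster_mean(fcs_map: FcsMap, roi: np.ndarray) -> float:
    """Mean FCS over roi intersected with the map's mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != fcs_map.data.shape:
        raise ValueError("roi shape does not match map")
    sel = roi & fcs_map.mask
    if not sel.any():
        raise ValueError("roi does not intersect the mask")
    return float(fcs_map.data[sel].mean())
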