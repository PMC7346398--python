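"""Core in-memory containers shared by every pipeline stage.

Spatial arrays follow the NIfTI convention (x, y, z[, t]); voxel indices
are 0-based throughout. Affines, when absent, default to a diagonal RAS+
affine built from the voxel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AG", "GG")


def _default_affine(voxel_size_mm: Tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


@dataclass
class BoldRun:
    """A single subject's 4D BOLD series with geometry and brain mask.

    data : float array, shape (x, y, z, t), arbitrary BOLD units
    tr_seconds : repetition time between volumes
    voxel_size_mm : physical voxel edge lengths
    mask : boolean (x, y, z) in-brain / gray-matter mask
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: Tuple[float, float, float]
    mask: np.ndarray
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"BoldRun.data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BoldRun.data must have t >= 2 volumes")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldRun.data contains non-finite values")
        if self.affine is None:
            self.affine = _default_affine(tuple(self.voxel_size_mm))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class MotionTrace:
    """Rigid-body motion parameters: t rows x 6 columns.

    Columns are 3 translations (mm) then 3 rotations (degrees), one row
    per retained volume.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"MotionTrace.params must be t x 6, got shape {self.params.shape}"
            )
        if self.params.shape[0] < 2:
            raise ValueError("MotionTrace needs at least 2 rows")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("MotionTrace.params contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def max_excursion(self) -> Tuple[float, float]:
        """Maximum absolute translation (mm) and rotation (degrees).

        Used to emulate excessive-motion exclusion rules of the
        '> 2.0 mm or > 2.0 degrees' kind.
        """
        trans = float(np.abs(self.params[:, :3]).max())
        rot = float(np.abs(self.params[:, 3:]).max())
        return trans, rot

    def discard_initial(self, n_discard: int) -> "MotionTrace":
        if n_discard >= self.n_volumes:
            raise ValueError("cannot discard all motion rows")
        return MotionTrace(self.params[n_discard:])


@dataclass
class NuisanceDesign:
    """Nuisance regression design matrix with named columns.

    With every component enabled the design has 28 columns:
    friston_1..friston_24, wm, csf, global, intercept.
    """

    matrix: np.ndarray
    column_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.column_names = tuple(self.column_names)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names length does not match matrix columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")
        if self.column_names.count("intercept") != 1:
            raise ValueError("design must contain exactly one intercept column")


@dataclass
class FcsMap:
    """Voxel-wise functional connectivity strength (weighted degree).

    FCS(i) = sum over other in-mask voxels j of atanh(r_ij) restricted to
    r_ij > r_threshold; ``scale='mean'`` divides by (n_mask - 1).
    """

    data: np.ndarray
    mask: np.ndarray
    r_threshold: float
    scale: str
    voxel_size_mm: Tuple[float, float, float]
    affine: Optional[np.ndarray] = None
    n_zero_variance: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("FcsMap data and mask shapes differ")
        if self.scale not in ("sum", "mean"):
            raise ValueError(f"scale must be 'sum' or 'mean', got {self.scale!r}")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("FcsMap has non-finite values inside the mask")
        if self.affine is None:
            self.affine = _default_affine(tuple(self.voxel_size_mm))


@dataclass
class StatMap:
    """A voxel-wise F or t statistic image with its degrees of freedom."""

    data: np.ndarray
    stat_kind: str  # "F" or "t"
    df: Tuple[float, ...]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.stat_kind not in ("F", "t"):
            raise ValueError("stat_kind must be 'F' or 't'")
        if self.stat_kind == "F" and len(self.df) != 2:
            raise ValueError("F maps need a (df1, df2) pair")
        if self.stat_kind == "t" and len(self.df) != 1:
            raise ValueError("t maps need a scalar df")
        if self.stat_kind == "F" and np.any(self.data[self.mask] < 0):
            raise ValueError("F values must be non-negative")


@dataclass
class SmoothnessEstimate:
    """Estimated spatial smoothness of the residual field.

    fwhm_vox : per-axis FWHM in voxel units
    resel_count : mask volume in resolution elements (resels)
    search_volume_vox : number of in-mask voxels
    """

    fwhm_vox: Tuple[float, float, float]
    resel_count: float
    search_volume_vox: int

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_vox):
            raise ValueError("FWHM components must be positive")
        if self.resel_count <= 0:
            raise ValueError("resel_count must be positive")


@dataclass
class ClusterTable:
    """Suprathreshold clusters surviving GRF cluster-level correction.

    ``table`` has one row per significant cluster: cluster_id, size_vox,
    peak_x, peak_y, peak_z, peak_stat, cluster_p_corrected (plus 'sign'
    for two-sided t maps). ``labels`` assigns each voxel its significant
    cluster id (0 = background). ``all_clusters`` additionally lists the
    clusters that did not survive, for diagnostics.
    """

    table: pd.DataFrame
    labels: np.ndarray
    voxel_forming_p: float
    cluster_alpha: float
    all_clusters: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if len(self.table):
            if (self.table["cluster_p_corrected"] > self.cluster_alpha).any():
                raise ValueError("reported cluster exceeds cluster_alpha")
            if (self.table["size_vox"] < 1).any():
                raise ValueError("cluster sizes must be >= 1")

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def significant_mask(self) -> np.ndarray:
        return self.labels > 0
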