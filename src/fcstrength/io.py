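"""File I/O: NIfTI volumes, motion text files, phenotype tables, results.

Volumes round-trip through NIfTI-1 with affine and voxel sizes
preserved. Phenotype tables are tab-separated with the schema
``subject_id genotype sex age spq_total spq_cogper spq_interp
spq_disorg``; the heterozygote spelling "GA" is normalized to "AG" with
a warning (both spellings occur in practice).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .types import GENOTYPES, BoldRun, FcsMap, MotionTrace

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "subject_id",
    "genotype",
    "sex",
    "age",
    "spq_total",
    "spq_cogper",
    "spq_interp",
    "spq_disorg",
]

PathLike = Union[str, Path]


def _voxel_sizes(img: nib.Nifti1Image) -> Tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_bold(
    bold_path: PathLike, mask_path: PathLike, tr_seconds: Optional[float] = None
) -> BoldRun:
    """Load a 4D BOLD NIfTI plus its 3D mask into a :class:`BoldRun`."""
    img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match BOLD spatial shape "
            f"{data.shape[:3]}"
        )
    if not np.allclose(mask_img.affine, img.affine, atol=1e-4):
        raise ValueError("mask and BOLD affines differ")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if not tr_seconds or tr_seconds <= 0:
        raise ValueError("TR not present in header; pass tr_seconds explicitly")
    return BoldRun(
        data=data,
        tr_seconds=tr_seconds,
        voxel_size_mm=_voxel_sizes(img),
        mask=mask,
        affine=img.affine,
    )


def write_bold(run: BoldRun, path: PathLike) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms(tuple(run.voxel_size_mm) + (run.tr_seconds,))
    nib.save(img, str(path))


def write_volume(
    data: np.ndarray, affine: np.ndarray, path: PathLike, dtype=np.float64
) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))


def read_volume(path: PathLike) -> Tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_fcs_map(fcs_map: FcsMap, path: PathLike) -> None:
    """Write an FCS map as NIfTI plus a JSON sidecar with its parameters."""
    write_volume(fcs_map.data, fcs_map.affine, path)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "r_threshold": fcs_map.r_threshold,
                "scale": fcs_map.scale,
                "n_zero_variance": fcs_map.n_zero_variance,
                "voxel_size_mm": list(fcs_map.voxel_size_mm),
            },
            indent=2,
        )
    )


def read_motion(path: PathLike) -> MotionTrace:
    """Read a whitespace- or tab-delimited 6-column motion file."""
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(
            f"motion file {path}: expected t x 6 columns, got shape {arr.shape}"
        )
    return MotionTrace(arr)


def write_motion(motion: MotionTrace, path: PathLike) -> None:
    np.savetxt(str(path), motion.params, fmt="%.6f", delimiter="\t")


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    """Read and validate the phenotype TSV.

    Genotype "GA" is normalized to "AG" with a warning; any other
    non-{AA, AG, GG} value raises with the line number and offending
    string. SPQ totals are bounded by the 74-item instrument.
    """
    df = pd.read_csv(str(path), sep="\t", dtype={"subject_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table {path}: missing columns {missing}")
    geno = df["genotype"].astype(str)
    ga = geno == "GA"
    if ga.any():
        warnings.warn(
            f"{int(ga.sum())} genotype value(s) 'GA' normalized to 'AG'"
        )
        geno = geno.where(~ga, "AG")
        df = df.assign(genotype=geno)
    for i, g in enumerate(geno):
        if g not in GENOTYPES:
            raise ValueError(
                f"phenotype table {path}, line {i + 2}: "
                f"genotype {g!r} is not one of {GENOTYPES}"
            )
    if (df["spq_total"] > 74).any() or (df["spq_total"] < 0).any():
        bad = df.index[(df["spq_total"] > 74) | (df["spq_total"] < 0)][0]
        raise ValueError(
            f"phenotype table {path}, line {bad + 2}: spq_total outside [0, 74]"
        )
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        i = df.index[bad_sex][0]
        raise ValueError(
            f"phenotype table {path}, line {i + 2}: sex must be male/female"
        )
    return df


def write_phenotypes(df: pd.DataFrame, path: PathLike) -> None:
    df[PHENOTYPE_COLUMNS].to_csv(str(path), sep="\t", index=False)


def write_cluster_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def read_cluster_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
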