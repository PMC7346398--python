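"""Voxel-wise genotype-group statistics and GRF cluster-level inference.

Three genetic codings of the rs204993 genotype are supported:

* ``additive``  — three groups (AA vs AG vs GG), one-way ANOVA F per voxel
* ``dominant``  — A-allele carriers (AA + AG) vs GG, two-sample t
* ``recessive`` — AA vs G-allele carriers (AG + GG), two-sample t

Cluster-level multiple-comparison correction follows the classical
Gaussian-random-field results for 3D fields: statistic maps are
converted to equivalent Z scores by p-value matching, thresholded at the
cluster-forming quantile, and each suprathreshold cluster of k voxels
receives the corrected probability

    P_corr = 1 - exp(-E[m] * P(n >= k)),

with E[m] the expected cluster count from the expected Euler
characteristic of a Z field over the estimated resel volume, and
P(n >= k) = exp(-beta * k^(2/3)) where beta is fixed by the expected
cluster size E[n] = E[suprathreshold volume] / E[m].

Field smoothness (FWHM per axis, hence resels) is estimated from the
first spatial differences of the voxelwise-standardized model residuals;
the procedure and its white-noise bias are documented in
:func:`estimate_smoothness`.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .types import GENOTYPES, ClusterTable, FcsMap, SmoothnessEstimate, StatMap

GENETIC_MODELS = ("additive", "dominant", "recessive")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _stack_maps(fcs_maps: Sequence[FcsMap]) -> Tuple[np.ndarray, np.ndarray]:
    mask = fcs_maps[0].mask
    for m in fcs_maps[1:]:
        if m.mask.shape != mask.shape or not np.array_equal(m.mask, mask):
            raise ValueError("all FCS maps must share grid and mask")
    y = np.stack([m.data[mask] for m in fcs_maps])  # N x V
    return y, mask


def _covariate_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object:
            levels = sorted(col.unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {name!r} has more than two levels")
            cols.append((col == levels[-1]).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def _residualize(y: np.ndarray, covariates: pd.DataFrame) -> Tuple[np.ndarray, int]:
    """OLS-residualize subject-by-voxel data on [intercept, covariates]."""
    c = _covariate_matrix(covariates)
    x = np.column_stack([np.ones(len(y)), c])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, c.shape[1]


def voxelwise_group_stat(
    fcs_maps: Sequence[FcsMap],
    genotypes: Sequence[str],
    model: str = "additive",
    covariates: Optional[pd.DataFrame] = None,
) -> Tuple[StatMap, List[np.ndarray]]:
    """Per-voxel group statistic under a genetic model, plus residual maps.

    Covariates (e.g. sex, age) are regressed out of the FCS values
    voxel-wise before the group test, with the error degrees of freedom
    reduced accordingly. Returns the statistic map and the per-subject
    residual maps from the group-mean model (raw residuals; smoothness
    estimation standardizes them).
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    genotypes = list(genotypes)
    bad = sorted(set(genotypes) - set(GENOTYPES))
    if bad:
        raise ValueError(f"unknown genotype labels: {bad}")
    if len(genotypes) != len(fcs_maps):
        raise ValueError("genotype labels and FCS maps differ in length")
    y, mask = _stack_maps(fcs_maps)
    n = len(genotypes)
    n_cov = 0
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate table length mismatch")
        y, n_cov = _residualize(y, covariates)

    geno = np.asarray(genotypes)
    if model == "additive":
        groups = [geno == g for g in GENOTYPES]
    elif model == "dominant":
        groups = [np.isin(geno, ("AA", "AG")), geno == "GG"]
    else:  # recessive
        groups = [geno == "AA", np.isin(geno, ("AG", "GG"))]
    counts = [int(g.sum()) for g in groups]
    if any(c < 2 for c in counts):
        raise ValueError(
            f"model {model!r} needs >= 2 subjects per cell, got {counts}"
        )

    means = [y[g].mean(axis=0) for g in groups]
    resid = y.copy()
    for g, m in zip(groups, means):
        resid[g] -= m
    sse = (resid ** 2).sum(axis=0)
    df2 = n - len(groups) - n_cov
    # voxels whose within-group variation is pure float noise get stat 0
    degenerate = sse <= 1e-24 * (y ** 2).sum(axis=0) + 1e-300

    grand = y.mean(axis=0)
    if model == "additive":
        ssb = sum(c * (m - grand) ** 2 for c, m in zip(counts, means))
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / 2) / (sse / df2)
        f = np.where(degenerate, 0.0, f)
        stat_kind, df, vals = "F", (2.0, float(df2)), f
    else:
        pooled = sse / df2
        se = np.sqrt(pooled * (1.0 / counts[0] + 1.0 / counts[1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (means[0] - means[1]) / se
        t = np.where(degenerate, 0.0, t)
        stat_kind, df, vals = "t", (float(df2),), t

    stat_img = np.zeros(mask.shape)
    stat_img[mask] = vals
    resid_maps = []
    for i in range(n):
        img = np.zeros(mask.shape)
        img[mask] = resid[i]
        resid_maps.append(img)
    return StatMap(stat_img, stat_kind, df, mask), resid_maps


def estimate_smoothness(
    residual_maps: Sequence[np.ndarray], mask: np.ndarray
) -> SmoothnessEstimate:
    """Per-axis FWHM and resel count from residual spatial derivatives.

    Residuals are standardized voxel-wise (divided by their root mean
    square across maps), then for each axis the mean square of first
    differences between adjacent in-mask voxels, pooled over maps, gives
    the derivative variance v_ax, and

        FWHM_ax = sqrt(4 ln 2 / v_ax).

    For i.i.d. Gaussian residuals (no smoothness) v_ax = 2, so the
    estimator returns sqrt(2 ln 2) ~ 1.1774 voxels — the analytic
    white-noise floor of the forward-difference estimator. The resel
    count sums resels-per-voxel over the mask:
    R = n_mask / prod(FWHM_ax).
    """
    if len(residual_maps) < 2:
        raise ValueError("need at least 2 residual maps")
    mask = np.asarray(mask, dtype=bool)
    res = np.stack([np.asarray(m, dtype=np.float64) for m in residual_maps])
    rms = np.sqrt((res ** 2).mean(axis=0))
    if np.any(rms[mask] == 0):
        raise ValueError("zero-variance residuals inside the mask")
    std = np.zeros_like(res)
    std[:, mask] = res[:, mask] / rms[mask]

    fwhm = []
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        pair = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        if not pair.any():
            raise ValueError(f"mask has no adjacent voxel pairs along axis {ax}")
        diffs = (
            std[(slice(None),) + tuple(sl_hi)] - std[(slice(None),) + tuple(sl_lo)]
        )[:, pair]
        v = float((diffs ** 2).mean())
        if v == 0:
            raise ValueError(f"degenerate (perfectly flat) residuals on axis {ax}")
        fwhm.append(math.sqrt(4.0 * math.log(2.0) / v))
    n_mask = int(mask.sum())
    resels = n_mask / float(np.prod(fwhm))
    return SmoothnessEstimate(tuple(fwhm), resels, n_mask)


def expected_cluster_count(u: float, resel_count: float) -> float:
    """Expected number of clusters of a unit Z field above ``u``.

    Expected Euler characteristic of a 3D Gaussian field over
    ``resel_count`` resels:
    E[m] = R * (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2).
    """
    return (
        resel_count
        * (4.0 * math.log(2.0)) ** 1.5
        * (2.0 * math.pi) ** -2
        * (u ** 2 - 1.0)
        * math.exp(-(u ** 2) / 2.0)
    )


def cluster_corrected_p(
    k_vox: int, u: float, smoothness: SmoothnessEstimate
) -> float:
    """GRF cluster-level corrected p for a cluster of ``k_vox`` voxels."""
    em = expected_cluster_count(u, smoothness.resel_count)
    if em <= 0:
        return 1.0
    en_vox = smoothness.search_volume_vox * stats.norm.sf(u) / em
    if en_vox <= 0:
        return 1.0
    beta = (math.gamma(2.5) / en_vox) ** (2.0 / 3.0)
    p_n = math.exp(-beta * k_vox ** (2.0 / 3.0))
    return float(1.0 - math.exp(-em * p_n))


def _zmap_from_stat(stat_map: StatMap, tail: int) -> np.ndarray:
    """Equivalent-Z map by p-value matching (one tail at a time)."""
    vals = stat_map.data
    if stat_map.stat_kind == "F":
        p = stats.f.sf(vals, *stat_map.df)
    else:
        p = stats.t.sf(tail * vals, stat_map.df[0])
    p = np.clip(p, 1e-300, 1.0)
    return stats.norm.isf(p)


def grf_cluster_inference(
    stat_map: StatMap,
    smoothness: SmoothnessEstimate,
    voxel_forming_p: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
) -> ClusterTable:
    """Cluster-level GRF correction of a voxel-wise statistic map.

    F maps are thresholded one-sidedly at ``voxel_forming_p``; t maps are
    treated as two one-sided passes at ``voxel_forming_p / 2`` each and
    clusters carry the sign of their tail. Clusters with corrected
    p <= ``cluster_alpha`` are reported; finding none yields an empty
    table.
    """
    if not 0 < voxel_forming_p < 1 or not 0 < cluster_alpha < 1:
        raise ValueError("voxel_forming_p and cluster_alpha must be in (0, 1)")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if smoothness is None:
        raise ValueError("smoothness estimate is required")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])

    if stat_map.stat_kind == "F":
        passes = [(+1, voxel_forming_p)]
    else:
        passes = [(+1, voxel_forming_p / 2.0), (-1, voxel_forming_p / 2.0)]

    rows: List[Dict] = []
    all_rows: List[Dict] = []
    labels = np.zeros(stat_map.mask.shape, dtype=np.int32)
    next_id = 1
    for tail, p_form in passes:
        u = float(stats.norm.isf(p_form))
        z = _zmap_from_stat(stat_map, tail)
        supra = (z >= u) & stat_map.mask
        lab, n_comp = ndimage.label(supra, structure=structure)
        for comp in range(1, n_comp + 1):
            sel = lab == comp
            k = int(sel.sum())
            p_corr = cluster_corrected_p(k, u, smoothness)
            stat_vals = stat_map.data[sel]
            peak_flat = int(np.argmax(tail * stat_vals))
            peak_xyz = tuple(int(c) for c in np.argwhere(sel)[peak_flat])
            row = {
                "size_vox": k,
                "peak_x": peak_xyz[0],
                "peak_y": peak_xyz[1],
                "peak_z": peak_xyz[2],
                "peak_stat": float(stat_vals[peak_flat]),
                "sign": tail,
                "cluster_p_corrected": p_corr,
            }
            all_rows.append(dict(row))
            if p_corr <= cluster_alpha:
                row["cluster_id"] = next_id
                labels[sel] = next_id
                next_id += 1
                rows.append(row)

    cols = [
        "cluster_id",
        "size_vox",
        "peak_x",
        "peak_y",
        "peak_z",
        "peak_stat",
        "sign",
        "cluster_p_corrected",
    ]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values("size_vox", ascending=False).reset_index(drop=True)
    all_df = pd.DataFrame(all_rows, columns=cols[1:])
    return ClusterTable(
        table=table,
        labels=labels,
        voxel_forming_p=voxel_forming_p,
        cluster_alpha=cluster_alpha,
        all_clusters=all_df,
    )


def posthoc_lsd(
    values: Sequence[float], genotypes: Sequence[str]
) -> pd.DataFrame:
    """Fisher least-significant-difference pairwise comparisons.

    Pairwise t tests on the group means using the pooled one-way ANOVA
    mean-square error and its degrees of freedom; p values are unadjusted
    (the LSD convention).
    """
    values = np.asarray(values, dtype=np.float64)
    genotypes = np.asarray(list(genotypes))
    levels = [g for g in GENOTYPES if g in genotypes] or sorted(set(genotypes))
    groups = [values[genotypes == g] for g in levels]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 subjects")
    n = len(values)
    k = len(groups)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
    df = n - k
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            if mse == 0:
                t = 0.0 if diff == 0 else math.inf * np.sign(diff)
                p = 1.0 if diff == 0 else 0.0
            else:
                se = math.sqrt(mse * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
                t = diff / se
                p = 2.0 * stats.t.sf(abs(t), df)
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": diff,
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)
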