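"""Cohort-level statistics: Hardy-Weinberg, demographics, ANOVA, Spearman.

These are the non-voxel tests of the analysis: a Hardy-Weinberg
chi-square on the genotype counts, a sex-by-genotype contingency
chi-square, one-way ANOVAs on age / SPQ / extracted FCS (computable from
raw values or directly from printed per-group n/mean/SD), an LSD post
hoc, and genotype-stratified Spearman correlations between the extracted
cluster FCS and the SPQ total and subscale scores at a Bonferroni-style
significance level p < 0.05 / divisor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import GENOTYPES


@dataclass
class SummaryStats:
    """Per-group sample size, mean and standard deviation."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def hwe_chi2(n_aa: int, n_ag: int, n_gg: int) -> Tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg equilibrium (1 df).

    Allele frequencies are taken from the genotype counts; expected
    counts are N*p^2, 2*N*p*q, N*q^2.
    """
    counts = np.array([n_aa, n_ag, n_gg], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p ** 2, 2 * p * q, q ** 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    chi2 = float(np.nansum(np.where(expected > 0, terms, 0.0)))
    return chi2, float(stats.chi2.sf(chi2, 1))


def contingency_chi2(table: Sequence[Sequence[int]]) -> Tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    arr = np.asarray(table, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def anova_from_summary(
    groups: Sequence[SummaryStats],
) -> Tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    SSB = sum n_i (mean_i - grand_mean)^2, SSW = sum (n_i - 1) sd_i^2;
    algebraically identical to the raw-data ANOVA with those moments.
    Returns (F, df1, df2, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=np.float64)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    k = len(groups)
    grand = (ns * means).sum() / n_total
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds ** 2).sum()
    df1 = k - 1
    df2 = int(n_total) - k
    if ssw == 0:
        f = math.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df1) / (ssw / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0


def oneway_anova(
    values: Sequence[float], labels: Sequence[str]
) -> Tuple[float, int, int, float]:
    """One-way ANOVA on raw per-subject values grouped by label."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(list(labels))
    levels = [g for g in GENOTYPES if g in labels] or sorted(set(labels))
    groups = [values[labels == g] for g in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 subjects")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = len(values) - len(groups)
    return float(f), df1, df2, float(p)


def spearman_by_group(
    brain_values: Sequence[float],
    scores: pd.DataFrame,
    genotypes: Sequence[str],
    alpha_divisor: int = 5,
    permutation: bool = False,
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-stratified Spearman correlations, brain vs each score.

    One row per (genotype group, score column) with rho, the two-tailed p
    (t approximation, or a permutation p when ``permutation=True``), and
    a significance flag at p < 0.05 / ``alpha_divisor``. A constant
    vector within a group leaves rho undefined: reported as NaN with a
    warning.
    """
    brain_values = np.asarray(brain_values, dtype=np.float64)
    genotypes = np.asarray(list(genotypes))
    if len(brain_values) != len(genotypes) or len(scores) != len(genotypes):
        raise ValueError("brain values, scores and genotypes differ in length")
    alpha = 0.05 / alpha_divisor
    rng = np.random.default_rng(seed)
    rows: List[Dict] = []
    for geno in (g for g in GENOTYPES if g in genotypes):
        sel = genotypes == geno
        if sel.sum() < 4:
            raise ValueError(f"group {geno} has fewer than 4 subjects")
        x = brain_values[sel]
        for col in scores.columns:
            y = scores[col].to_numpy(dtype=np.float64)[sel]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant vector in group {geno} for {col}: rho undefined"
                )
                rows.append(
                    {"genotype": geno, "score": col, "n": int(sel.sum()),
                     "rho": np.nan, "p": np.nan, "significant": False}
                )
                continue
            rho, p = stats.spearmanr(x, y)
            if permutation:
                rx = stats.rankdata(x)
                ry = stats.rankdata(y)
                obs = abs(np.corrcoef(rx, ry)[0, 1])
                perm = np.array(
                    [
                        abs(np.corrcoef(rng.permutation(rx), ry)[0, 1])
                        for _ in range(n_permutations)
                    ]
                )
                p = float((1 + (perm >= obs - 1e-12).sum()) / (1 + n_permutations))
            rows.append(
                {
                    "genotype": geno,
                    "score": col,
                    "n": int(sel.sum()),
                    "rho": float(rho),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)
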