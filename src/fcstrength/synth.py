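"""Synthetic multi-subject resting-state cohort with a genotype-dosed hub.

The generator emulates the structure the downstream analysis assumes: a
cohort of three rs204993 genotype groups (AA, AG, GG), one BOLD run and
one rigid-body motion trace per subject, a phenotype table with SPQ
schizotypal-trait scores, and a ground-truth record for
parameter-recovery tests.

Connectivity is seeded through a shared band-limited latent time course:
every voxel of a small spherical "hub" follows

    sqrt(d) * latent + sqrt(1 - d) * noise

where the dose ``d`` depends on the subject's genotype (plus a
subject-level jitter), so hub voxels correlate with the latent signal at
sqrt(d) and with each other at roughly sqrt(d_i * d_j). Non-hub voxels
are independent noise. On top of the signal, every voxel receives
spatially global nuisance components — simulated white-matter and CSF
time courses, a global low-frequency drift, and a motion-coupled signal —
which is exactly what the nuisance-regression stage is meant to remove.

Schizotypal scores are drawn per group from specified moments; within one
designated genotype group the total SPQ score is coupled to the subject's
hub dose at a specified correlation (``behavior_coupling``), mirroring a
genotype-specific brain-behavior association.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import reference
from .types import GENOTYPES, BoldRun, MotionTrace

# SPQ subscale item counts (cognitive-perceptual, interpersonal,
# disorganized). Subscales share items, so counts sum past 74.
_SUBSCALE_ITEMS = (33, 33, 16)

# Amplitudes of the injected nuisance components, relative to noise_sd.
_NUIS_AMP = {"wm": 0.3, "csf": 0.3, "global": 0.5, "motion": 0.2}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; reproducible from ``seed``."""

    group_sizes: Tuple[int, int, int] = reference.GENOTYPE_COUNTS
    grid_shape: Tuple[int, int, int] = (16, 16, 10)
    n_volumes: int = reference.N_VOLUMES
    tr_seconds: float = reference.TR_SECONDS
    hub_center: Tuple[int, int, int] = (8, 8, 5)
    hub_radius_vox: float = 2.5
    connectivity_dose: Tuple[float, float, float] = (0.2, 0.45, 0.7)
    spq_means: Tuple[float, float, float] = reference.SPQ_SUMMARY["mean"]
    spq_sds: Tuple[float, float, float] = reference.SPQ_SUMMARY["sd"]
    behavior_coupling: float = -0.4
    coupled_group: str = "GG"
    noise_sd: float = 1.0
    motion_sd: float = 0.05
    dose_jitter_sd: float = 0.05
    voxel_size_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    latent_band_hz: Tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("group_sizes: need three groups of size >= 2")
        if len(self.grid_shape) != 3 or int(np.prod(self.grid_shape)) < 27:
            raise ValueError("grid_shape: product must be >= 27")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes: must be > 10")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds: must be positive")
        if any(not (-1 < d < 1) for d in self.connectivity_dose):
            raise ValueError("connectivity_dose: values must lie in (-1, 1)")
        if not (self.connectivity_dose[0] <= self.connectivity_dose[1]
                <= self.connectivity_dose[2]):
            raise ValueError("connectivity_dose: must be ordered AA <= AG <= GG")
        if self.hub_radius_vox <= 0:
            raise ValueError("hub_radius_vox: must be positive")
        r = self.hub_radius_vox
        for ax, (c, n) in enumerate(zip(self.hub_center, self.grid_shape)):
            if c - r < 0 or c + r > n - 1:
                raise ValueError(
                    f"hub_center: hub (radius {r}) extends outside the grid "
                    f"on axis {ax}"
                )
        if not -1 <= self.behavior_coupling <= 1:
            raise ValueError("behavior_coupling: must lie in [-1, 1]")
        if self.coupled_group not in GENOTYPES:
            raise ValueError(f"coupled_group: unknown genotype {self.coupled_group!r}")
        if any(s <= 0 for s in self.spq_sds):
            raise ValueError("spq_sds: must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd: must be positive")
        if self.motion_sd < 0:
            raise ValueError("motion_sd: must be non-negative")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.group_sizes))


@dataclass
class CohortTruth:
    """Generator ground truth used by parameter-recovery tests."""

    hub_mask: np.ndarray
    per_subject_hub_strength: np.ndarray
    genotype_labels: List[str]
    effect_ordering: Tuple[str, ...] = ("AA", "AG", "GG")

    def __post_init__(self) -> None:
        self.hub_mask = np.asarray(self.hub_mask, dtype=bool)
        if not self.hub_mask.any():
            raise ValueError("hub_mask is empty")
        if len(self.genotype_labels) != len(self.per_subject_hub_strength):
            raise ValueError("labels and hub strengths differ in length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "hub_voxels": np.argwhere(self.hub_mask).tolist(),
                "grid_shape": list(self.hub_mask.shape),
                "per_subject_hub_strength": self.per_subject_hub_strength.tolist(),
                "genotype_labels": list(self.genotype_labels),
                "effect_ordering": list(self.effect_ordering),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortTruth":
        obj = json.loads(text)
        mask = np.zeros(obj["grid_shape"], dtype=bool)
        for idx in obj["hub_voxels"]:
            mask[tuple(idx)] = True
        return cls(
            hub_mask=mask,
            per_subject_hub_strength=np.asarray(obj["per_subject_hub_strength"]),
            genotype_labels=obj["genotype_labels"],
            effect_ordering=tuple(obj["effect_ordering"]),
        )


def hub_mask_for(spec: CohortSpec) -> np.ndarray:
    """Boolean ball of radius ``hub_radius_vox`` around ``hub_center``."""
    grids = np.indices(spec.grid_shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, spec.hub_center))
    return d2 <= spec.hub_radius_vox ** 2


def tissue_masks(spec: CohortSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(gray-matter, white-matter, CSF) masks on the simulation grid.

    Two 3x3x3 corner boxes stand in for WM and CSF; gray matter is the
    remainder. The hub must not intersect the corner boxes.
    """
    shape = spec.grid_shape
    wm = np.zeros(shape, dtype=bool)
    csf = np.zeros(shape, dtype=bool)
    wm[:3, :3, :3] = True
    csf[-3:, -3:, -3:] = True
    gm = ~(wm | csf)
    return gm, wm, csf


def generate_motion(
    n_volumes: int, motion_sd: float, seed: int | np.random.Generator = 0
) -> MotionTrace:
    """Smooth random-walk rigid-body motion trace (t x 6).

    Each column is a cumulative sum of i.i.d. Gaussian steps of standard
    deviation ``motion_sd``, lightly smoothed with a 5-point moving
    average; ``motion_sd = 0`` yields an all-zero trace.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    if motion_sd < 0:
        raise ValueError("motion_sd must be non-negative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    steps = rng.normal(0.0, motion_sd, size=(n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.apply_along_axis(
        lambda c: np.convolve(np.pad(c, 2, mode="edge"), kernel, mode="valid"),
        0,
        walk,
    )
    return MotionTrace(smooth)


def _band_limited_signal(
    n: int, tr: float, band: Tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance random signal with power confined to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    coef = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep the lowest nonzero bin
        keep = np.zeros_like(keep)
        keep[1] = True
    coef[~keep] = 0.0
    sig = np.fft.irfft(coef, n=n)
    sig -= sig.mean()
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def draw_subject_table(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Subject-level phenotypes and ground-truth doses (no imaging).

    Returns one row per subject: subject_id, genotype, sex, age, the four
    SPQ scores, and the true connectivity dose. Within ``coupled_group``
    the total SPQ is correlated with the standardized dose at
    ``behavior_coupling``; in the other groups the coupling is zero.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rows = []
    sub = 0
    for g_idx, (geno, n_g) in enumerate(zip(GENOTYPES, spec.group_sizes)):
        dose_mean = spec.connectivity_dose[g_idx]
        z_dose = rng.normal(size=n_g)
        doses = np.clip(dose_mean + spec.dose_jitter_sd * z_dose, 0.01, 0.99)
        eps = rng.normal(size=n_g)
        rho_s = spec.behavior_coupling if geno == spec.coupled_group else 0.0
        # behavior_coupling targets the rank (Spearman) correlation, the
        # statistic the analysis measures; on the Gaussian latent scale
        # that is a Pearson coupling of 2 sin(pi * rho_s / 6).
        rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
        spq_z = rho * z_dose + np.sqrt(1.0 - rho ** 2) * eps
        spq_total = np.clip(
            np.rint(spec.spq_means[g_idx] + spec.spq_sds[g_idx] * spq_z), 0, 74
        ).astype(int)
        # Subscales scale with the total per their item shares plus noise;
        # shares sum past 1 because SPQ subscales share items.
        shares = np.array(_SUBSCALE_ITEMS) / 74.0
        subs = np.clip(
            np.rint(spq_total[:, None] * shares[None, :]
                    + rng.normal(0.0, 1.5, size=(n_g, 3))),
            0,
            np.array(_SUBSCALE_ITEMS),
        ).astype(int)
        sexes = rng.permuted(
            np.array(["male", "female"])[(np.arange(n_g) % 2)]
        )
        ages = np.clip(np.rint(rng.normal(20.9, 1.1, size=n_g)), 18, 25).astype(int)
        for i in range(n_g):
            sub += 1
            rows.append(
                {
                    "subject_id": f"sub-{sub:03d}",
                    "genotype": geno,
                    "sex": sexes[i],
                    "age": ages[i],
                    "spq_total": spq_total[i],
                    "spq_cogper": subs[i, 0],
                    "spq_interp": subs[i, 1],
                    "spq_disorg": subs[i, 2],
                    "hub_dose": doses[i],
                }
            )
    return pd.DataFrame(rows)


def _subject_bold(
    spec: CohortSpec,
    dose: float,
    gm: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    hub: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[BoldRun, MotionTrace]:
    nt = spec.n_volumes
    shape = spec.grid_shape
    motion = generate_motion(nt, spec.motion_sd, rng)

    latent = _band_limited_signal(nt, spec.tr_seconds, spec.latent_band_hz, rng)
    nuis_wm = _band_limited_signal(nt, spec.tr_seconds, (0.0, 0.05), rng)
    nuis_csf = _band_limited_signal(nt, spec.tr_seconds, (0.0, 0.05), rng)
    drift = _band_limited_signal(nt, spec.tr_seconds, (0.0, 0.02), rng)
    mot_weights = rng.normal(size=6)
    mot_sig = motion.params @ mot_weights
    sd = mot_sig.std()
    if sd > 0:
        mot_sig = (mot_sig - mot_sig.mean()) / sd

    data = spec.noise_sd * rng.normal(size=shape + (nt,))
    # Hub: shared latent at genotype-dosed correlation (on the amplitude
    # convention sqrt(d) * latent + sqrt(1 - d) * noise).
    amp_lat = np.sign(dose) * np.sqrt(abs(dose))
    amp_noise = np.sqrt(1.0 - abs(dose))
    data[hub] = spec.noise_sd * (
        amp_lat * latent[None, :]
        + amp_noise * rng.normal(size=(int(hub.sum()), nt))
    )
    # Spatially global nuisance structure (everywhere, hub included).
    global_nuis = (
        _NUIS_AMP["wm"] * nuis_wm
        + _NUIS_AMP["csf"] * nuis_csf
        + _NUIS_AMP["global"] * drift
        + _NUIS_AMP["motion"] * mot_sig
    )
    data += spec.noise_sd * global_nuis[None, None, None, :]
    # Extra tissue-specific weight so WM/CSF mask means estimate their
    # own nuisance time course.
    data[wm] += spec.noise_sd * nuis_wm[None, :]
    data[csf] += spec.noise_sd * nuis_csf[None, :]

    run = BoldRun(
        data=data,
        tr_seconds=spec.tr_seconds,
        voxel_size_mm=spec.voxel_size_mm,
        mask=gm,
    )
    return run, motion


def iter_subject_runs(
    spec: CohortSpec, table: Optional[pd.DataFrame] = None
) -> Iterator[Tuple[BoldRun, MotionTrace]]:
    """Yield (BoldRun, MotionTrace) per subject without holding the cohort.

    Deterministic: subject k always sees the same random stream for a
    given ``spec.seed``, whether generated lazily or via
    :func:`generate_cohort`.
    """
    if table is None:
        table = draw_subject_table(spec)
    gm, wm, csf = tissue_masks(spec)
    hub = hub_mask_for(spec)
    for k, row in enumerate(table.itertuples()):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, k]))
        yield _subject_bold(spec, row.hub_dose, gm, wm, csf, hub, rng)


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[List[BoldRun], List[MotionTrace], pd.DataFrame, CohortTruth]:
    """Generate the full cohort: BOLD runs, motion, phenotypes, truth."""
    spec.validate()
    table = draw_subject_table(spec)
    runs: List[BoldRun] = []
    motions: List[MotionTrace] = []
    for run, motion in iter_subject_runs(spec, table):
        runs.append(run)
        motions.append(motion)
    truth = CohortTruth(
        hub_mask=hub_mask_for(spec),
        per_subject_hub_strength=table["hub_dose"].to_numpy(),
        genotype_labels=table["genotype"].tolist(),
        effect_ordering=GENOTYPES,
    )
    return runs, motions, table, truth


def phenotype_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Phenotype table in the on-disk schema (truth columns dropped)."""
    cols = [
        "subject_id",
        "genotype",
        "sex",
        "age",
        "spq_total",
        "spq_cogper",
        "spq_interp",
        "spq_disorg",
    ]
    return table[cols].copy()
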