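"""Pipeline configuration: every analysis constant as a named default.

The configuration round-trips losslessly through YAML. Defaults mirror
the reference analysis: discard 5 volumes, band-pass 0.01-0.1 Hz with
global signal regression, FCS threshold r = 0.1 with 4 mm FWHM
smoothing, GRF correction at voxel p < 0.001 / cluster p < 0.05, and
stratified Spearman significance at p < 0.05/5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from . import reference
from .inference import GENETIC_MODELS


@dataclass
class PipelineConfig:
    # paths (None => simulate a cohort instead of loading one)
    bold_pattern: Optional[str] = None
    mask_path: Optional[str] = None
    motion_pattern: Optional[str] = None
    phenotype_path: Optional[str] = None
    output_dir: str = "fcstrength_out"
    # simulation
    simulate: bool = True
    group_sizes: Tuple[int, int, int] = reference.GENOTYPE_COUNTS
    grid_shape: Tuple[int, int, int] = (16, 16, 10)
    n_volumes: int = reference.N_VOLUMES
    connectivity_dose: Tuple[float, float, float] = (0.2, 0.45, 0.7)
    behavior_coupling: float = -0.4
    # preprocessing
    n_discard: int = reference.N_DISCARD
    band_hz: Tuple[float, float] = reference.BAND_HZ
    global_signal_regression: bool = True
    # FCS
    r_threshold: float = reference.R_THRESHOLD
    fcs_scale: str = "mean"
    smooth_fwhm_mm: float = reference.SMOOTH_FWHM_MM
    # inference
    models: Tuple[str, ...] = GENETIC_MODELS
    voxel_forming_p: float = reference.VOXEL_FORMING_P
    cluster_alpha: float = reference.CLUSTER_ALPHA
    connectivity: int = 26
    covariates: Tuple[str, ...] = ("sex", "age")
    # behavior
    alpha_divisor: int = reference.SPEARMAN_ALPHA_DIVISOR
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.voxel_forming_p < 1:
            raise ValueError("voxel_forming_p must be in (0, 1)")
        if not 0 < self.cluster_alpha < 1:
            raise ValueError("cluster_alpha must be in (0, 1)")
        if self.fcs_scale not in ("sum", "mean"):
            raise ValueError("fcs_scale must be 'sum' or 'mean'")
        unknown = [m for m in self.models if m not in GENETIC_MODELS]
        if unknown:
            raise ValueError(f"unknown genetic model(s): {unknown}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if not 0 <= self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must satisfy 0 <= low < high")
        if self.alpha_divisor < 1:
            raise ValueError("alpha_divisor must be >= 1")
        if self.n_discard < 0:
            raise ValueError("n_discard must be non-negative")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, val in d.items():
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
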