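"""Published reference-cohort description for the rs204993 genotype groups.

These are the printed summary statistics of the 402-subject NOTCH4
rs204993 cohort (genotype groups AA / AG / GG) that the synthetic-data
generator emulates and that the cohort-level statistics are checked
against. They are inputs to the package, not outputs of it.
"""

from __future__ import annotations

# Genotype counts in (AA, AG, GG) order.
GENOTYPE_COUNTS = (142, 188, 72)

# Sex counts, rows (male, female), columns (AA, AG, GG).
SEX_TABLE = ((68, 88, 41), (74, 100, 31))

# Per-group (n, mean, sd) in (AA, AG, GG) order.
AGE_SUMMARY = {
    "n": GENOTYPE_COUNTS,
    "mean": (20.761, 20.942, 21.097),
    "sd": (1.104, 1.061, 1.115),
}

SPQ_SUMMARY = {
    "n": GENOTYPE_COUNTS,
    "mean": (26.930, 26.553, 31.167),
    "sd": (13.853, 14.038, 14.470),
}

# Mean FCS extracted from the group-difference cluster in occipital cortex.
FCS_SUMMARY = {
    "n": GENOTYPE_COUNTS,
    "mean": (0.379, 0.612, 0.755),
    "sd": (0.461, 0.531, 0.542),
}

# Acquisition defaults the simulator mirrors.
TR_SECONDS = 2.4
N_VOLUMES = 217
N_DISCARD = 5

# Analysis defaults.
BAND_HZ = (0.01, 0.1)
R_THRESHOLD = 0.1
SMOOTH_FWHM_MM = 4.0
VOXEL_FORMING_P = 0.001
CLUSTER_ALPHA = 0.05
SPEARMAN_ALPHA_DIVISOR = 5
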