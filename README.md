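# fcstrength

Voxel-wise **functional connectivity strength** (FCS) analysis for
resting-state fMRI imaging genetics: preprocessing, weighted
degree-centrality mapping, genotype-group inference with
Gaussian-random-field cluster correction, and genotype-stratified
brain-behavior statistics — plus a synthetic cohort generator with
ground truth for end-to-end validation.

It is written for researchers studying how a common genetic variant
(here the *NOTCH4* SNP rs204993, genotypes AA/AG/GG) modulates
resting-state brain connectivity and its association with schizotypal
traits measured by the 74-item SPQ questionnaire.

## The statistics at the core

For each in-mask voxel *i* of a preprocessed BOLD run, FCS is the
Fisher-transformed, thresholded weighted degree:

> FCS(i) = Σ_{j≠i} atanh(r_ij) · 1[r_ij > 0.1]

optionally divided by the number of other in-mask voxels (`scale=mean`).
Preprocessing discards 5 volumes, regresses out the Friston-24 motion
expansion plus white-matter/CSF/global signals, and band-passes
0.01–0.1 Hz. Smoothed (4 mm FWHM) FCS maps are compared across genotype
groups under additive (3-group ANOVA), dominant and recessive (2-group
t) models; voxel p < 0.001 defines clusters whose family-wise corrected
p comes from the classical 3D Gaussian-random-field results

> P_corr = 1 − exp(−E[m]·P(n ≥ k)),  E[m] = R·(4 ln 2)^{3/2}(2π)^{−2}(u²−1)e^{−u²/2}

with resel count R estimated from standardized-residual spatial
derivatives. Cluster-mean FCS is then tested by one-way ANOVA with LSD
post hoc, and correlated (Spearman, p < 0.05/5) with SPQ total and
subscale scores within each genotype group. Details, defaults and
numerical choices: [docs/methods.md](docs/methods.md).

## Worked example

Run the full pipeline on a synthetic 60-subject cohort with a
genotype-dosed connectivity hub:

```python
from fcstrength import PipelineConfig
from fcstrength.pipeline import run_pipeline

cfg = PipelineConfig(group_sizes=(20, 20, 20), output_dir="demo_run", seed=1)
results = run_pipeline(cfg)
print(results["models"]["additive"]["n_significant_clusters"])
print(results["cluster_extraction"]["group_means"])
print(results["recovery"])
```

prints

```
2
{'AA': 0.0326815323408055, 'AG': 0.034136262318736066, 'GG': 0.036349219390810455}
{'dice_vs_true_hub': 0.30740037950664134, 'ordering_correct': True}
```

— the additive model finds two significant clusters; the extracted
cluster-mean FCS rises monotonically from AA through AG to GG (the dosed
ordering); and the significant-cluster set overlaps the true seeded hub
(Dice 0.31). `demo_run/` contains the statistic and cluster-label
NIfTIs, cluster tables, LSD post hoc, stratified Spearman results and a
provenance record.

The same stages are available from the shell:

```bash
fcstrength simulate --out sim --seed 1
fcstrength preprocess --bold sim/bold_sub-001.nii.gz --mask sim/mask.nii.gz \
    --motion sim/motion_sub-001.txt --wm sim/wm_mask.nii.gz \
    --csf sim/csf_mask.nii.gz --out resid.nii.gz
fcstrength fcs --bold resid.nii.gz --mask sim/mask.nii.gz --out fcs_sub-001.nii.gz
fcstrength run --out full_run --seed 1
```

Cohort-level statistics work directly from published per-group
summaries:

```python
from fcstrength import hwe_chi2, anova_from_summary, SummaryStats

chi2, p = hwe_chi2(142, 188, 72)           # (0.5046, 0.4775)
f, df1, df2, p = anova_from_summary([
    SummaryStats(142, 0.379, 0.461),
    SummaryStats(188, 0.612, 0.531),
    SummaryStats(72, 0.755, 0.542),
])                                          # F(2, 399) = 15.20
```

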