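# Methods

`fcstrength` implements a voxel-wise imaging-genetics analysis of
resting-state fMRI: per-subject functional connectivity strength (FCS)
maps, genotype-group inference under three genetic models with
Gaussian-random-field (GRF) cluster-level correction, and
genotype-stratified brain-behavior correlations. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic cohort does and does not emulate.

## Preprocessing

The package assumes spatially registered 4D BOLD input (slice-timing
correction, realignment and template normalization are upstream of this
package). The chain is fixed and ordered:

1. **Volume discarding** — the first `n_discard` volumes (default 5) are
   dropped to allow longitudinal magnetization to stabilize; the motion
   trace is trimmed identically.
2. **Nuisance regression** — ordinary least squares of every in-mask
   voxel series on a design of the Friston-24 motion expansion
   `[R, R², R₋₁, R₋₁²]` (the autoregressive form: the six rigid-body
   parameters, their squares, their one-volume lags and squared lags,
   first lag row zero-padded), the mean white-matter and CSF time
   courses, the global (whole-mask) mean time course, and an intercept —
   28 columns in total. Global signal regression is on by default and
   switchable (`--no-gsr`). Exactly collinear columns are dropped with a
   logged warning, never silently. Residuals replace the data; out-of-mask
   voxels are zeroed.
3. **Band-pass filtering** — an ideal DFT-domain mask on the linearly
   detrended residual series: rFFT bins with frequency in
   `[low, high]` = [0.01, 0.1] Hz pass with unit gain, all others
   (including DC) are zeroed. The transfer function is therefore exactly
   the indicator of the band on the DFT grid. An ideal mask was chosen
   over a Butterworth filter because its gain is fully documented by one
   sentence and testable bin-by-bin.

Whether regression should precede filtering is a genuinely open ordering
question in resting-state pipelines; this package fixes
regression-then-filter and records it here (simultaneous band-limited
regression is the known alternative, not implemented).

All computation is double precision.

## Functional connectivity strength

For in-mask voxel *i* with preprocessed series *xᵢ*:

    FCS(i) = Σ_{j≠i} atanh(r_ij) · 1[r_ij > r_thr]

with Pearson `r_ij`, Fisher's variance-stabilizing `atanh`, and a strict
positive threshold `r_thr = 0.1` that excludes weak and negative
correlations (ties at exactly 0.1 are excluded; no negative-FCS variant
is provided). Correlations are clipped to ±(1 − 1e−7) before `atanh` so
duplicate series cannot produce infinities. Exactly constant series get
FCS = 0 and are counted in `n_zero_variance`.

Two scales are exposed: `sum` (the literal definition) and `mean`
(divided by the number of in-mask voxels minus one). Reported group FCS
values in the high-resolution literature (≈0.4–0.8) are incompatible
with a raw sum over tens of thousands of voxels, implying some
normalization that the verbal definition leaves unstated; `mean` is the
default for reporting and `sum` reproduces the definition verbatim. The
correlation matrix is processed in row blocks (default 2048 rows) so the
V×V matrix is never materialized for large masks; block and dense paths
are tested for exact agreement.

Maps are smoothed with a Gaussian kernel of 4 mm FWHM
(σ_axis = FWHM / (voxel_size · √(8 ln 2))), restricted to the mask and
renormalized by the smoothed mask so out-of-mask zeros do not bleed in
(a constant map stays constant).

## Genotype-group inference

Three codings of the rs204993 genotype: **additive** (AA vs AG vs GG
one-way ANOVA F per voxel, df = (2, N−3)), **dominant** (A-carriers vs
GG two-sample t), **recessive** (AA vs G-carriers two-sample t).
Demographic covariates (sex, age) are adjusted by voxel-wise
residualization of the FCS values on `[1, covariates]` before the group
test, with the error df reduced by the number of covariates; the upstream
analysis names no specific adjustment mechanism, and residualization is
the transparent choice.

**Smoothness estimation.** GRF correction needs the residual field's
smoothness, whose estimation the source analyses leave to their
toolboxes; this package adopts the standardized-residual derivative
estimator: residuals are divided voxel-wise by their root-mean-square
over subjects, and per axis

    FWHM_ax = sqrt(4 ln 2 / v_ax),

where `v_ax` is the mean square of first differences between adjacent
in-mask voxels pooled over subjects. For i.i.d. residuals the estimator
returns its analytic floor √(2 ln 2) ≈ 1.1774 voxels (asserted in the
tests); for fields smoothed at 3 voxels FWHM it is accurate to within
~4% (the forward difference slightly overestimates FWHM of smooth
fields). Resels are summed per voxel: `R = n_mask / Π FWHM_ax`.

**Cluster-level correction.** Statistic maps are converted to equivalent
Z by p-value matching (F one-sidedly; t maps as two one-sided passes at
half the forming p, clusters carrying their tail's sign), thresholded at
the Z quantile of the forming p (default 0.001), and labelled by
26-connectivity (6/18 switchable). A cluster of k voxels receives

    P_corr = 1 − exp(−E[m] · P(n ≥ k)),
    E[m]   = R · (4 ln 2)^{3/2} (2π)^{−2} (u² − 1) e^{−u²/2},
    P(n≥k) = exp(−β k^{2/3}),  β = (Γ(5/2) / E[n])^{2/3},
    E[n]   = V_mask · Φ(−u) / E[m],

the classical 3D Gaussian-field forms (expected Euler characteristic for
the cluster count; the 2/3-power tail for cluster extent). Clusters with
`P_corr ≤ 0.05` are reported.

**Calibration and its limits.** Monte-Carlo null simulations (smooth
Gaussian subject maps, study-scale groups of 134, grid 18×18×12,
smoothness 4 voxels FWHM — inside the ≥3-voxel regime random-field
theory assumes) give a family-wise rate of ~0.05 at nominal 0.05. At
lower smoothness the correction is **conservative**, severely so by 2
voxels FWHM (near-zero false positives): the extent-tail approximation
overstates P(n ≥ k) for small expected cluster sizes, and converting
low-df F to Z shrinks realized clusters further. Conservatism errs safe
for detection claims but costs power at low smoothness.

Corrected p is monotone decreasing in cluster size. It is *not* monotone
in resel count for fixed k: roughness raises the expected cluster count
but shrinks null cluster sizes, and in the operating regime the second
effect dominates (a fixed 20-voxel cluster is more surprising in a
rougher field).

**Post hoc.** Fisher LSD: pairwise t tests on the group means using the
pooled one-way-ANOVA mean square error and its df, unadjusted p values.

## Cohort-level statistics

* Hardy-Weinberg: allele frequencies from the genotype counts, expected
  counts Np², 2Npq, Nq², Pearson χ² with 1 df.
* Sex-by-genotype: Pearson χ² of independence without continuity
  correction (the continuity-uncorrected statistic is what reproduces
  published 2×3 values).
* One-way ANOVA either from raw values or reconstructed exactly from
  per-group (n, mean, SD): SSB = Σnᵢ(meanᵢ−grand)², SSW = Σ(nᵢ−1)sdᵢ².
  The two routes are algebraically identical and tested against each
  other to 1e−10 (the raw route goes through `scipy.stats.f_oneway`, the
  summary route is closed-form here, so the identity is a genuine
  cross-check).
* Stratified Spearman: per genotype group and score, rho with average
  ranks, two-tailed p by the t approximation (adequate for groups of
  ≥~70; an exact permutation p is available behind a flag for small
  groups), significance at p < 0.05/divisor with divisor 5 by default.
  The divisor is kept at the literal published 5 even though only four
  correlations (total + three subscales) are tested; it is a parameter.

## Synthetic cohort generator

The generator emulates the *structure* the analysis assumes, with ground
truth for recovery tests. Defaults mirror the reference cohort: groups
(142, 188, 72), TR 2.4 s, 217 volumes, SPQ moments per group from the
published table; grid 16×16×10 at a nominal 2 mm isotropic voxel size so
that all-pairs correlation (≈2500 in-mask voxels) runs at desk scale.

* **Hub connectivity.** A band-limited (0.01–0.08 Hz) latent time course
  is shared by all voxels of a spherical hub (radius 2.5 voxels); hub
  voxel series are `sqrt(d)·latent + sqrt(1−d)·noise` with dose *d* set
  by genotype — defaults (0.2, 0.45, 0.7) for (AA, AG, GG) — plus a
  subject-level jitter (SD 0.05). Under this amplitude convention the
  hub-latent correlation is √d and hub-hub correlations ≈ √(dᵢdⱼ); the
  band limitation ensures the seeded effect survives the band-pass
  stage. Non-hub voxels are independent noise.
* **Nuisance structure.** Simulated WM and CSF time courses, a global
  low-frequency drift and a motion-coupled signal are added as spatially
  global components to *all* voxels (hub included — they are global by
  construction), with extra weight inside the WM/CSF corner boxes so the
  extracted tissue means actually estimate them. This gives the
  regression stage something real to remove.
* **Motion** is a lightly smoothed Gaussian random walk per rigid-body
  parameter; `motion_sd = 0` yields an exactly zero trace. Maximum
  excursions are reported so exclusion rules of the "> 2 mm / 2°" kind
  can be emulated.
* **Behavior coupling.** Within one designated genotype group (default
  GG) the total SPQ is coupled to the subject's hub dose at a target
  *rank* correlation `behavior_coupling` (default −0.4, the order of the
  published GG association); on the Gaussian latent scale this is a
  Pearson coupling of 2 sin(π·ρ/6) (the Gaussian-copula inverse), chosen
  because the analysis statistic is Spearman. Subscale scores follow the
  total according to their item shares (33/33/16 of 74 — subscales share
  items, so no sum constraint is imposed or asserted). Scores are
  rounded to integers and clipped to the instrument range, which
  attenuates realized correlations by a few hundredths.
* **Determinism.** Each subject draws from a child seed of the cohort
  seed, so streamed and collected generation produce byte-identical
  data.

What the generator does **not** emulate: scanner physics, spatial
autocorrelation of the noise floor (non-hub noise is spatially white
before smoothing), anatomical variability, registration error, distance-
dependent motion artifacts, or any real spatial layout of tissue
(WM/CSF are corner boxes). Passing recovery tests therefore shows the
*pipeline* is correct and calibrated under its own assumptions — not
that those assumptions hold in acquired data.

## Problem sizes used in the test suite

Chosen so the whole suite runs comfortably on one CPU: FWE calibration
uses 200 null simulations (18×18×12 grid, 134 subjects per group,
smoothness 4 voxels); hub recovery uses 10 cohorts of 20 subjects per
group on the default 16×16×10 grid; the stratified-correlation check
uses 50 replicates at the full published group sizes; the null
hub-calibration check uses 50 reduced cohorts (10×10×8, 4 per group).

## Known limitations

* GRF cluster correction is conservative below ~3 voxels smoothness (see
  above); permutation inference is out of scope.
* Peak-level (voxel-wise FWE) correction is not implemented — cluster
  level only.
* No separation of local vs long-range connectivity contributions to
  FCS.
* `anova_from_summary` on 3-decimal published moments inherits their
  rounding: reconstructed F statistics agree with published ones to
  ~1–2%, not exactly.
* When loading a real cohort without tissue masks, the pipeline driver
  falls back to motion + global regression only; supply WM/CSF masks for
  the full design.
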