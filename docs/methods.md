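# Methods

## The measurement model

Gadolinium-based contrast agents shorten T1 where they accumulate.  With a
quantitative T1 map acquired before and a few minutes after injection, the
voxelwise difference ΔT1 = T1_post − T1_pre (ms) is a per-voxel measure of
early tracer enhancement; regional per-subject medians are the analysis
unit.  The scientific questions addressed by the statistics stage are (a)
whether enhancement differs between daytime (06:00–17:59) and nighttime
(18:00–05:59) scans after adjusting for age, sex and diagnosis, and (b)
how enhancement changes per year of age within each period.

Because no patient data are distributed, everything is validated by
**parameter recovery on synthetic data**: generators are configured with
published summary values, and the pipeline plus statistics must measure
those values back.

## Synthetic cohort (tier 1)

One row per subject; regional ΔT1 follows an additive linear model

    ΔT1_r = μ_r(period) + β_r(period) · (age − 63) + sex/diagnosis offsets
            + N(0, σ_r)

* **μ_r, β_r** default to the published per-region day/night medians and
  age slopes (e.g. daytime cerebral cortex μ = −166.4 ms, β = −0.47
  ms/year).  The day/night effect enters as period-specific intercepts
  (medians are reported per period), and the age effect is additive with
  period — the published interaction tests were all null, so the generator
  contains no interaction and the analysis stage tests for one it knows to
  be absent.  The true generative form in vivo is unknown.
* **σ_r** (between-subject SD): 22 ms for cortical regions, back-derived
  so that a normal distribution reproduces the reported ~29 ms cortical
  interquartile width (IQR = 1.349 σ); non-cortical regions use the same
  IQR-derivation (cerebral WM 9, cerebellar WM 11, basal-ganglia PVS 20,
  choroid plexus 108 ms).
* **Age**: truncated normal, mean 63.0, SD 13.3, bounds [18, 95] years
  (only mean±SD and median/IQR are reported; truncation keeps ages
  physiologic).  The reference age of the linear predictor is 63.
* **Sex / diagnosis**: categorical draws with per-period proportions taken
  from the published day/night contingency tables (six classes: IPD, ET,
  MSA, PSP, VaP, Other).  Their ΔT1 offsets default to 0 — no effect sizes
  are reported — and exist so covariate adjustment can be exercised with
  nonzero values in tests.
* **Scan clock**: uniform over each 720-minute period window (the true
  acquisition-time distribution is unreported); the day/night label is
  derived from the clock, never stored independently.
* **Contrast delay**: log-normal with median 5.9 min and σ_log = 0.1239
  (matching the reported 5.5–6.5 IQR width; a log-normal cannot match the
  slightly asymmetric printed quartiles and the median exactly, the median
  is matched exactly).  It is metadata, not a model covariate.

## Brain phantom (tier 2)

Analytic shapes on a ≥48³ voxel grid (default 128³ at 1.5 mm isotropic):
a cerebrum sphere whose outer shell (5% of grid extent) is cortex,
subdivided into four lobes per hemisphere by 90° sectors in the sagittal
plane; white matter inside; a central ventricle with two choroid-plexus
blobs on its walls; left/right basal-ganglia blobs each threaded by three
tubes of 1.1-voxel radius in varied orientations (ground-truth PVS); and a
separate cerebellum sphere.  The geometry is exactly mirror-symmetric
about the mid-sagittal plane (tested by reflect-and-compare), and grids
with voxels on the midplane are rejected so left/right structures are
strictly separated.

Rendering assigns 3T-plausible pre-contrast T1 values (cortex 1400, WM
850, basal ganglia 1300, CSF 4000, CP 2200 ms — placeholders: only ΔT1 is
quantified), subtracts a per-region enhancement magnitude for the
post-contrast map, and adds independent Gaussian voxel noise to the pre
and post maps.  T1-weighted images are a monotone decreasing map of T1
(∝ 1/T1, scaled to [0, 1000] a.u.), which makes CSF-filled spaces dark —
the only property consumed downstream.  **Partial-volume effects, bias
fields and gyrification are not modelled.**  Consequences: region edges
are hard intensity steps, and the thin structures (cortex shell, PVS
tubes) are only a few voxels across.  Passing tests on this phantom
demonstrate correct propagation of enhancement through the pipeline, not
robustness to anatomy-scale confounds of real acquisitions.

## Rigid registration

6 parameters (intrinsic x-y-z Euler rotations in degrees about the volume
center, translations in mm, RAS+ world coordinates = voxel index × voxel
size); the transform serializes as a 4×4 homogeneous matrix.  The cost is
the mean squared intensity difference on the fixed grid, minimized with
bounded Powell search (derivative-free) through a 3-level Gaussian
pyramid, initialized at identity with a ±10 mm / ±10° capture range
(same-session scans).  Numerical choices that matter on hard-edged
volumes:

* at the finest level the moving image is sampled with a **cubic-spline
  image model** and the cost is evaluated on a stride-2 subgrid; the
  trilinear SSD of voxelized edges is not smooth in subvoxel shifts and
  its minimum can sit 0.2–0.4° away from the true pose, which the cubic
  model removes at ~⅓ the full-grid cost;
* an optional `finest_sigma` band-limits both images at full resolution
  (default 1 voxel inside the pyramid levels);
* if the optimized cost does not improve on the initialization (relative
  margin 1e-6), the identity transform is returned with a `failed` status
  and a warning — on an already-aligned pair the identity is genuinely
  optimal and tiny parameter jitter triggers this path harmlessly.

Known-transform recovery on a band-limited phantom (|t| ≤ 4 mm,
|θ| ≤ 5°) is within 0.2 mm / 0.2°; rotations are the weakly determined
directions because the dominant phantom edges are spheres.

Resampling uses trilinear interpolation for intensity volumes and nearest
neighbour for labels (trilinear on integer label volumes is rejected).
Because the phantom has no partial-volume smoothing, *any* subvoxel
resample blends the 1–3-voxel thin structures with their neighbours and
biases their medians; the pipeline therefore defaults to zero simulated
inter-scan motion (as in same-session acquisitions, where misregistered
cases would be excluded) and motion is a config knob used by the
registration tests.

## Segmentation

**PVS** (on the registered pre-contrast T1-weighted image): histogram
equalization maps within-brain intensities through their empirical CDF
onto (0, 1] (rank-preserving; equalization scope is within the brain
mask); multiscale Frangi vesselness with σ ∈ {1, 1.5, 2} voxels, α = β =
0.5, per-scale structureness constant c = half the maximal Hessian
Frobenius norm (data-driven, standard practice), **dark-tube polarity**
λ2 > 0 ∧ λ3 > 0 (PVS are hypointense on T1w); the basal-ganglia parcel is
closed then dilated with a 2-voxel spherical element; the threshold is
**τ = mean + 1 population SD** of the vesselness inside the refined mask,
with a strict inequality so a zero-variance response yields an empty (not
arbitrary) segmentation; voxels above τ split left/right at the grid
midplane (adequate for the midplane-symmetric phantom; real data would
need an anatomical midline).  Gaussian-derivative kernels are
moment-corrected so that constants are annihilated exactly — Frangi output
is exactly invariant to intensity shifts — and second derivatives of
quadratics are exact, which makes the closed-form eigenvalue tests sharp.
σ is interpreted in voxels (the phantom is isotropic).

**Choroid plexus**: a K = 2 Gaussian mixture is fitted by EM to
post-contrast T1-weighted intensities within an initial CP + ventricle
mask.  Initialization is deterministic (component means at the
(k−½)/K quantiles, equal weights, pooled variance), variances are floored
at 1e-10 × data variance on collapse, and the log-likelihood trace is
checked monotone.  Voxels are assigned by maximum posterior
responsibility; the higher-mean component is CP (enhancing tissue is
bright post-contrast, CSF dark).  A mean gap below half the pooled
within-component SD triggers a "poorly separated" warning but still
returns the assignment.

## Quantification and statistics

ΔT1 excludes voxels with nonpositive T1 in either input (set missing);
medians/IQRs use the linear-interpolation quantile definition; empty
regions are flagged missing rather than reported as zero.  PVS and CP
rows use the *segmented* masks in the main path, with ground-truth-mask
rows emitted alongside for validation.

Models are ordinary least squares with Wald t tests; rank-deficient
designs are rejected with the offending columns named.  Treatment coding:
diagnosis reference `Other`, sex reference `male`, period reference
`night` (the period coefficient is then the adjusted day−night
difference).  Covariates degenerate in a given cohort (one observed
level, zero variance) are dropped, so an ANCOVA without covariate
variation reduces *exactly* to the pooled two-sample t-test.  The
Mann–Whitney U test enumerates exactly for n ≤ 8 per group without ties,
otherwise uses the tie- and continuity-corrected normal approximation;
chi-square applies Yates continuity correction to 2×2 tables only (which
reproduces the published sex-table p = 0.562); pairwise Fisher exact
tests (two-sided, point-probability convention) are Bonferroni-adjusted
by the number of row pairs — 15 for six diagnosis classes, which
reproduces the published adjusted p ≈ 0.013.  No multiplicity correction
is applied across regions, mirroring the reported analysis.

## Validation protocol sizes

Chosen as the smallest sizes at which Monte-Carlo error is comfortably
inside the recovery tolerances: phantom runs use one 96³ volume per
day/night condition with 20 ms voxel noise (cortex median MC error
≈ 0.3 ms, CP ≈ 1.6 ms); slope recovery uses 20 replicate cohorts at the
study's stratum sizes (mean-slope MC error ≈ 0.02 day / 0.03 night
ms/year against ±0.1 tolerances); the ANCOVA type-I error uses 500 null
replicates (binomial SE ≈ 0.01).  The default end-to-end demo runs a 64³
phantom and a 40-subject cohort.

## Known limitations

* The phantom's hard edges and thin structures make regional medians
  sensitive to any resampling; quantification accuracy is therefore
  demonstrated on aligned pairs, and motion robustness only at the level
  of transform recovery.
* The L/R split is the grid midplane, not an anatomical midline.
* The cohort model is linear-Gaussian with independent regions; real ΔT1
  distributions are mildly skewed and spatially correlated.
* Histogram-equalization scope, the GMM's K and assignment rule, and the
  morphology radius are under-specified in the source description; the
  choices above (within-mask CDF, K = 2 higher-mean-is-CP, radius 2) are
  fixed and documented for reproducibility.
* Deep-learning segmentation (the nnU-Net stage trained on these
  classical labels) and FreeSurfer/SynthSeg parcellation are out of
  scope; the phantom's ground-truth labels stand in for the latter.
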