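# earlygad

Quantitative analysis of **early-phase gadolinium enhancement** in the
brain, as used to probe glymphatic (perivascular fluid-transport)
function: after an intravenous gadolinium-based contrast agent (GBCA)
shortens tissue T1, the voxelwise change

ΔT1 = T1<sub>post</sub> − T1<sub>pre</sub>  (ms, more negative = stronger enhancement)

measured a few minutes post-injection reflects early tracer influx and
retention.  The package reimplements, on fully synthetic data, an analysis
pipeline for testing whether early cortical enhancement differs between
**daytime (06:00–17:59)** and **nighttime (18:00–05:59)** scans and how it
changes with **age**:

1. **Synthetic cohort generator** — a 447-subject tabular cohort
   (307 day / 140 night; age, sex, six movement-disorder diagnosis
   classes, scan clock time, contrast delay) with regional ΔT1 drawn from
   an additive linear model
   `ΔT1_r = μ_r(period) + β_r(period)·(age − 63) + offsets + N(0, σ_r)`.
2. **Brain phantom** — a deterministic 3-D parcellation (cortical lobes
   L/R, white matter, cerebellum, basal ganglia with ground-truth
   perivascular-space (PVS) tubes, ventricle, choroid plexus (CP)) rendered
   into pre/post-contrast T1 maps (ms) and T1-weighted images, NIfTI-1 I/O.
3. **Rigid registration** — 6-DOF (3 rotations + 3 translations),
   least-squares intensity cost, Powell search over a 3-level Gaussian
   pyramid.
4. **Segmentation** — the classical PVS rule: histogram equalization →
   multiscale Frangi vesselness (dark tubes, σ ∈ {1, 1.5, 2} voxels) →
   basal-ganglia mask closing+dilation → threshold τ = mean + 1 SD of the
   in-mask vesselness → hemispheric split; CP refined from an initial
   CP+ventricle mask by a 2-component Gaussian-mixture EM on post-contrast
   intensities.
5. **Quantification** — regional median [IQR] ΔT1 per subject/region.
6. **Statistics** — ANCOVA of ΔT1 on scan period adjusted for age, sex and
   diagnosis; age slopes (β, ms/year) per period; age × period interaction;
   Mann–Whitney U, chi-square and pairwise Bonferroni-adjusted Fisher exact
   tests for the baseline tables.

It is aimed at researchers who want a tested, reproducible reference
implementation of this analysis style — e.g. to benchmark segmentation or
registration components against known ground truth, or to run power/type-I
error simulations for day/night designs.

## Worked example

```python
import earlygad as eg

# cohort + statistics
cohort = eg.generate_cohort(seed=1)          # 447 subjects, ΔT1 per region
beta, p = eg.age_slope_by_period(cohort, "cerebral_cortex", "day")
print(len(cohort), round(beta, 3), f"{p:.2e}")
```

prints

```
447 -0.389 7.08e-05
```

447 subjects were generated; the daytime stratified regression (adjusting
for sex and diagnosis) recovers an age slope of −0.389 ms/year against the
generative −0.47 (single-cohort sampling error ≈ ±0.09) — each additional year of age deepens daytime cortical
ΔT1 by about half a millisecond — with p ≈ 1e-4.

```python
# imaging pipeline on the phantom
from earlygad import validation
m = validation.phantom_regional_medians("day", seed=1)
print({k: round(v, 1) for k, v in m.items() if isinstance(v, float)})
```

prints

```
{'cerebral_cortex': -166.3, 'cerebral_white_matter': -38.9, 'choroid_plexus': -871.1}
```

The phantom was rendered with enhancement magnitudes of 166.4 (cortex),
39.3 (white matter) and 869.7 ms (choroid plexus) plus 20 ms voxel noise;
after registration, ΔT1 computation, Gaussian-mixture CP segmentation and
median summarization the pipeline reads those values back.

An end-to-end run (cohort CSV, NIfTI volumes, masks, summaries, statistics
tables, checksummed manifest) is one command:

```bash
earlygad all --out demo_run --seed 7
```

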