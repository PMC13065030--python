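"""Reproduction protocols: the study-condition checks the package can run
without patient data.

The clinical measurements themselves are not reproducible (the cohort is
not deposited), so validation is parameter *recovery*: the generators are
configured with the published summary values (cohort structure, regional
ΔT1 medians, age slopes) and the pipeline plus statistics stage must
measure those values back.  Each function here runs one such protocol from
scratch and returns the measured quantities; the acceptance script and the
acceptance tests both call them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import cohort as cohort_mod
from .cohort import GenerativeParams
from .phantom import build_label_volume, render_t1_pair
from .quantify import compute_delta_t1, regional_medians
from .registration import register_rigid, resample
from .segmentation import segment_cp
from .stats import age_slope_by_period

#: Table of generative per-region enhancement magnitudes (ms, positive =
#: T1 reduction) for the phantom, by period.  These are the negated
#: published daytime/nighttime regional ΔT1 medians; basal-ganglia tissue
#: (not reported separately) gets a nominal 40 ms.
PHANTOM_ENHANCEMENT = {
    "day": {
        "cerebral_cortex": 166.4,
        "cerebellar_cortex": 174.6,
        "cerebral_white_matter": 39.3,
        "cerebellar_white_matter": 50.4,
        "basal_ganglia": 40.0,
        "bg_pvs": 87.2,
        "choroid_plexus": 869.7,
    },
    "night": {
        "cerebral_cortex": 160.9,
        "cerebellar_cortex": 165.0,
        "cerebral_white_matter": 38.4,
        "cerebellar_white_matter": 50.3,
        "basal_ganglia": 40.0,
        "bg_pvs": 88.5,
        "choroid_plexus": 869.2,
    },
}


def cohort_demographics(seed: int = 0) -> dict:
    """Generate the default study-size cohort and summarize its structure."""
    table = cohort_mod.generate_cohort(seed=seed)
    return {
        "n": len(table),
        "n_day": int((table.scan_period == "day").sum()),
        "n_night": int((table.scan_period == "night").sum()),
        "mean_age": float(table.age.mean()),
        "delay_median": float(table.contrast_delay.median()),
        "cortex_day_median": float(
            table.loc[table.scan_period == "day", "cerebral_cortex"].median()
        ),
    }


def phantom_regional_medians(
    period: str = "day",
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 1.5,
    noise_sd: float = 20.0,
) -> dict:
    """Run the imaging pipeline on one phantom and report regional medians.

    Renders a pre/post T1 pair with the period's enhancement magnitudes and
    voxel noise, registers the pre-contrast T1-weighted image to the
    post-contrast one (same-session pair: the estimated transform verifies
    alignment), applies the transform to the pre-contrast T1 map, computes
    ΔT1, segments the choroid plexus with the Gaussian-mixture refinement,
    and summarizes regional medians.
    """
    labels = build_label_volume(shape, voxel_size)
    vols = render_t1_pair(
        labels, PHANTOM_ENHANCEMENT[period], noise_sd=noise_sd, seed=seed
    )
    transform, info = register_rigid(
        vols["t1w_pre"], vols["t1w_post"], voxel_size=voxel_size
    )
    t1_pre_reg = resample(vols["t1_pre"], transform, voxel_size)
    delta = compute_delta_t1(t1_pre_reg, vols["t1_post"])
    cp = segment_cp(
        vols["t1w_post"], labels.mask("choroid_plexus") | labels.mask("ventricle")
    )
    summary = regional_medians(delta, labels, cp_mask=cp).set_index("region")
    return {
        "cerebral_cortex": float(summary.loc["cerebral_cortex", "median"]),
        "cerebral_white_matter": float(summary.loc["cerebral_white_matter", "median"]),
        "choroid_plexus": float(summary.loc["choroid_plexus", "median"]),
        "registration_status": info["status"],
    }


def recovered_age_slope(
    region: str,
    period: str,
    n_replicates: int = 20,
    seed: int = 0,
    subject_sd: float = 22.0,
) -> float:
    """Mean fitted age slope (ms/year) over replicate simulated strata.

    Each replicate simulates one stratum at the study size (307 daytime or
    140 nighttime subjects) from the default generative model with the
    given between-subject SD, then fits the stratified regression
    (ΔT1 ~ age + sex + diagnosis).
    """
    base = GenerativeParams()
    params = replace(
        base,
        regions={region: replace(base.regions[region], subject_sd=subject_sd)},
    )
    n_day, n_night = (307, 0) if period == "day" else (0, 140)
    betas = []
    for r in range(n_replicates):
        table = cohort_mod.generate_cohort(
            params, n_day=n_day, n_night=n_night, seed=(seed + 7919 * (r + 1)) % 2**31
        )
        beta, _ = age_slope_by_period(table, region, period)
        betas.append(beta)
    return float(np.mean(betas))
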