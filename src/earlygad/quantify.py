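"""Voxelwise ΔT1 and regional median summaries.

ΔT1 = post-contrast T1 minus registered pre-contrast T1 (ms); gadolinium
enhancement shortens T1, so enhancement appears as negative ΔT1.  Regions
are summarized by the per-subject median with interquartile range, over
the parcellation (cortex as the union of lobes, white matter, cerebellum)
plus the segmented PVS and choroid-plexus masks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import LabelVolume
from .segmentation import PvsSegmentationResult

#: summary rows, in report order: (region name, how the mask is obtained)
SUMMARY_REGIONS = (
    "cerebral_cortex",
    "cerebellar_cortex",
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "occipital_cortex",
    "cerebral_white_matter",
    "cerebellar_white_matter",
    "bg_pvs",
    "choroid_plexus",
)


def compute_delta_t1(pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Voxelwise post - pre (ms); voxels with nonpositive T1 in either
    input are set to NaN (missing)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(f"grid mismatch: pre {pre.shape} vs post {post.shape}")
    delta = post - pre
    delta[(pre <= 0) | (post <= 0)] = np.nan
    return delta


def _summarize(delta: np.ndarray, mask: np.ndarray, region: str) -> dict:
    values = delta[mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        return {
            "region": region, "n_voxels": 0,
            "median": np.nan, "q1": np.nan, "q3": np.nan, "missing": True,
        }
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return {
        "region": region, "n_voxels": int(values.size),
        "median": float(med), "q1": float(q1), "q3": float(q3), "missing": False,
    }


def regional_medians(
    delta: np.ndarray,
    labels: LabelVolume,
    pvs: PvsSegmentationResult | np.ndarray | None = None,
    cp_mask: np.ndarray | None = None,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Median [IQR] ΔT1 per analyzed region.

    Parcellation regions come from ``labels``; PVS and CP rows use the
    segmented masks when given (falling back to the ground-truth labels
    otherwise).  With ``include_truth`` the truth-mask PVS/CP summaries are
    appended as ``*_truth`` rows for validation.  Empty regions are flagged
    ``missing`` rather than silently reported as zero.
    """
    if delta.shape != labels.grid.shape:
        raise ValueError("delta map and label volume must share a grid")
    rows = []
    for region in SUMMARY_REGIONS:
        if region == "bg_pvs":
            if pvs is None:
                mask = labels.mask("bg_pvs")
            elif isinstance(pvs, PvsSegmentationResult):
                mask = pvs.mask
            else:
                mask = np.asarray(pvs, dtype=bool)
        elif region == "choroid_plexus":
            mask = (
                np.asarray(cp_mask, dtype=bool)
                if cp_mask is not None
                else labels.mask("choroid_plexus")
            )
        else:
            mask = labels.mask(region)
        rows.append(_summarize(delta, mask, region))
    if include_truth:
        rows.append(_summarize(delta, labels.mask("bg_pvs"), "bg_pvs_truth"))
        rows.append(
            _summarize(delta, labels.mask("choroid_plexus"), "choroid_plexus_truth")
        )
    return pd.DataFrame(rows)
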