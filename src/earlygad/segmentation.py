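"""Rule-based segmentation of basal-ganglia PVS and choroid plexus.

PVS pipeline (on the pre-contrast T1-weighted image):

1. standardize intensities by histogram equalization (within-mask
   empirical-CDF mapping to [0, 1]);
2. Frangi vesselness tuned to dark tubes at scales 1-2 voxels;
3. refine the basal-ganglia mask by binary closing then dilation with a
   spherical structuring element;
4. threshold the vesselness at τ = mean + 1 SD of the response inside the
   refined mask (population SD; strict inequality, so a zero-variance
   response yields an empty segmentation);
5. assign separate left/right labels at the mid-sagittal plane.

Choroid plexus: a two-component 1-D Gaussian mixture (EM, quantile
initialization) is fitted to post-contrast T1-weighted intensities within
an initial CP+ventricle mask; the enhancing CP is the higher-mean
component (gadolinium shortens T1, raising T1-weighted intensity, while
ventricular CSF stays dark).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import ball

from .vesselness import VesselnessParams, frangi_vesselness

logger = logging.getLogger(__name__)


# -------------------------------------------------- intensity standardization


def standardize_histogram(t1w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Histogram equalization: map within-mask intensities by their
    empirical CDF onto (0, 1].

    Rank order is preserved (ties share a value via mid-ranks); voxels
    outside the mask are set to 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("standardization mask is empty")
    values = np.asarray(t1w, dtype=float)[mask]
    ranks = stats.rankdata(values, method="average")
    out = np.zeros(t1w.shape, dtype=np.float64)
    out[mask] = ranks / values.size
    return out


# ----------------------------------------------------------- mask refinement


def refine_bg_mask(bg_mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """Binary closing then dilation with a spherical structuring element.

    The output is guaranteed to be a superset of the input.  An empty
    input yields an empty output with a warning.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not bg_mask.any():
        warnings.warn("refine_bg_mask: input mask is empty", stacklevel=2)
        return bg_mask.copy()
    se = ball(radius)
    closed = ndimage.binary_closing(bg_mask, structure=se)
    dilated = ndimage.binary_dilation(closed, structure=se)
    return dilated | bg_mask


# ------------------------------------------------------------ PVS segmentation


def mean_plus_sd_threshold(values: np.ndarray) -> tuple[float, float, float]:
    """τ = mean + 1 population SD of the in-mask vesselness response.

    Returns (tau, mean, sd)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a threshold on an empty sample")
    mean = float(values.mean())
    sd = float(values.std())  # population SD (divide by n)
    return mean + sd, mean, sd


@dataclass
class PvsSegmentationResult:
    """Left/right PVS masks plus the threshold bookkeeping."""

    mask_left: np.ndarray
    mask_right: np.ndarray
    threshold_tau: float
    mask_mean: float
    mask_sd: float
    refined_bg_mask: np.ndarray
    vesselness: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.mask_left | self.mask_right


def segment_pvs(
    t1w: np.ndarray,
    bg_mask: np.ndarray,
    params: VesselnessParams | None = None,
    radius: int = 2,
    brain_mask: np.ndarray | None = None,
) -> PvsSegmentationResult:
    """Segment basal-ganglia PVS on a (registered) T1-weighted image.

    ``bg_mask`` is the binary basal-ganglia parcel; ``brain_mask`` (default:
    nonzero voxels of ``t1w``) is the domain of histogram standardization.
    The threshold is τ = mean + 1 population SD of the vesselness inside
    the refined basal-ganglia mask; voxels strictly above τ are PVS, split
    into left/right at the grid mid-sagittal plane (first axis).
    """
    params = params or VesselnessParams()
    if brain_mask is None:
        brain_mask = np.asarray(t1w) != 0
    standardized = standardize_histogram(t1w, brain_mask)
    vness = frangi_vesselness(standardized, params)
    refined = refine_bg_mask(bg_mask, radius=radius)
    tau, mean, sd = mean_plus_sd_threshold(vness[refined])
    if sd == 0.0:
        logger.warning("segment_pvs: zero-variance vesselness in mask; empty result")
    pvs = refined & (vness > tau)
    half = t1w.shape[0] // 2
    left = np.zeros_like(pvs)
    left[:half] = pvs[:half]
    right = np.zeros_like(pvs)
    right[half:] = pvs[half:]
    return PvsSegmentationResult(
        mask_left=left,
        mask_right=right,
        threshold_tau=tau,
        mask_mean=mean,
        mask_sd=sd,
        refined_bg_mask=refined,
        vesselness=vness,
    )


# -------------------------------------------------------- 1-D Gaussian mixture


@dataclass
class GmmModel:
    """1-D Gaussian mixture fitted by EM."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_components(self) -> int:
        return len(self.means)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (n, K)."""
        x = np.asarray(x, dtype=float)[:, None]
        log_pdf = (
            -0.5 * np.log(2 * np.pi * self.variances)
            - (x - self.means) ** 2 / (2 * self.variances)
        )
        log_w = np.log(self.weights) + log_pdf
        log_norm = np.logaddexp.reduce(log_w, axis=1, keepdims=True)
        return np.exp(log_w - log_norm)


def fit_gmm_1d(
    values: np.ndarray,
    n_components: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-10,
) -> GmmModel:
    """Fit a K-component 1-D Gaussian mixture by EM.

    Initialization is deterministic: component means at the (k - 1/2)/K
    quantiles of the data, equal weights, pooled variance.  The
    log-likelihood trace is monotone non-decreasing; variances are floored
    at ``var_floor`` times the data variance (flagged via warning) to
    survive degenerate collapse.
    """
    x = np.asarray(values, dtype=float).ravel()
    K = int(n_components)
    if K < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < 2 * K:
        raise ValueError(f"need at least {2 * K} data points for K={K}")
    data_var = max(float(np.var(x)), 1e-300)
    floor = var_floor * data_var

    q = (np.arange(K) + 0.5) / K
    means = np.quantile(x, q)
    variances = np.full(K, data_var / K**2 + floor)
    weights = np.full(K, 1.0 / K)
    model = GmmModel(weights, means, variances)

    prev_ll = -np.inf
    for _ in range(max_iter):
        resp = model.responsibilities(x)
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        if np.any(variances < floor):
            warnings.warn("fit_gmm_1d: variance collapse, flooring", stacklevel=2)
            variances = np.maximum(variances, floor)
        model = GmmModel(weights, means, variances, model.log_likelihood)
        ll = _log_likelihood(model, x)
        model.log_likelihood.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            model.converged = True
            break
        prev_ll = ll
    return model


def _log_likelihood(model: GmmModel, x: np.ndarray) -> float:
    xx = x[:, None]
    log_pdf = (
        -0.5 * np.log(2 * np.pi * model.variances)
        - (xx - model.means) ** 2 / (2 * model.variances)
    )
    return float(np.logaddexp.reduce(np.log(model.weights) + log_pdf, axis=1).sum())


# ------------------------------------------------------------ CP segmentation


def segment_cp(
    t1w_post: np.ndarray,
    initial_mask: np.ndarray,
    n_components: int = 2,
) -> np.ndarray:
    """Refine an initial CP+ventricle mask into a choroid-plexus mask.

    Within-mask post-contrast T1-weighted intensities are clustered with a
    Gaussian mixture; voxels are assigned by maximum posterior
    responsibility and the higher-mean cluster (the enhancing tissue) is
    returned as CP.  If the components are poorly separated (mean gap
    below half the pooled SD) a warning is issued but the assignment is
    still returned.
    """
    initial_mask = np.asarray(initial_mask, dtype=bool)
    if not initial_mask.any():
        raise ValueError("initial CP mask is empty")
    x = np.asarray(t1w_post, dtype=float)[initial_mask]
    if np.ptp(x) == 0:  # single effective component: everything is CP
        return initial_mask.copy()
    model = fit_gmm_1d(x, n_components=n_components)
    resp = model.responsibilities(x)
    assignment = np.argmax(resp, axis=1)
    top = int(np.argmax(model.means))
    others = [k for k in range(model.n_components) if k != top]
    if others:
        pooled_sd = float(np.sqrt(model.variances.mean()))
        gap = float(model.means[top] - max(model.means[k] for k in others))
        if pooled_sd > 0 and gap < 0.5 * pooled_sd:
            warnings.warn(
                "segment_cp: mixture components poorly separated "
                f"(gap {gap:.3g} < 0.5 x pooled SD {pooled_sd:.3g})",
                stacklevel=2,
            )
    cp = np.zeros(t1w_post.shape, dtype=bool)
    idx = np.flatnonzero(initial_mask.ravel())
    cp.ravel()[idx[assignment == top]] = True
    return cp


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
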