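"""Multiscale Hessian (Frangi) vesselness for dark tubular structures.

Perivascular spaces are thin CSF-filled tubes, hypointense on T1-weighted
images, so the filter is run in "dark tube" polarity: at a tube voxel the
two cross-sectional second derivatives are large and positive
(λ2, λ3 > 0) while the along-tube derivative λ1 is small.  The per-scale
response is

    V_σ = (1 - exp(-R_A²/2α²)) · exp(-R_B²/2β²) · (1 - exp(-S²/2c²))

with R_A = |λ2|/|λ3| (plate vs line), R_B = |λ1|/√|λ2 λ3| (blob),
S = √(λ1²+λ2²+λ3²) (structureness), eigenvalues sorted by magnitude
|λ1| ≤ |λ2| ≤ |λ3| from the σ²-normalized Gaussian-scale Hessian, and the
response maximized over scales.  Default scales σ ∈ {1.0, 1.5, 2.0} voxels
target tubes of roughly 1-2 voxel radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_HESSIAN_ORDERS = {
    (0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
    (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1),
}


def _gaussian_derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with exact moment correction.

    The raw sampled kernels do not annihilate constants / reproduce
    polynomial derivatives exactly, which would break intensity-shift
    invariance of the Hessian; the kernels are therefore corrected to have
    an exact vanishing zeroth moment (orders 1, 2) and an exact unit
    response on x (order 1) and x² -> 2 (order 2).
    """
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -x / sigma**2 * phi  # odd: zero-sum by symmetry
        resp = (k * x).sum()  # normalize so the response on a ramp is 1
        return k / resp
    if order == 2:
        k = (x**2 / sigma**2 - 1.0) / sigma**2 * phi
        k -= phi * (k.sum() / phi.sum())  # annihilate constants exactly
        resp = (k * x**2).sum()  # response on x^2 must be 2
        return k * (2.0 / resp)
    raise ValueError("order must be 0, 1 or 2")


def _gaussian_derivative(volume: np.ndarray, sigma: float, orders) -> np.ndarray:
    out = volume
    for axis, order in enumerate(orders):
        k = _gaussian_derivative_kernel(sigma, order)
        out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
    return out


@dataclass(frozen=True)
class VesselnessParams:
    """Frangi filter parameters.

    ``c`` is the structureness scale; when ``None`` it is set per scale to
    half the maximum Hessian Frobenius norm over the volume (the usual
    data-driven choice).  ``polarity`` selects dark tubes on a bright
    background (the PVS case) or the reverse.
    """

    scales: tuple[float, ...] = (1.0, 1.5, 2.0)
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None
    polarity: str = "dark_tubes"

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("at least one scale is required")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be positive")
        if self.polarity not in ("dark_tubes", "bright_tubes"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def hessian_eigenvalues(volume: np.ndarray, sigma: float) -> np.ndarray:
    """Eigenvalues of the scale-normalized Gaussian Hessian.

    Returns an array of shape ``volume.shape + (3,)`` with eigenvalues
    sorted by absolute value (|λ1| ≤ |λ2| ≤ |λ3|) at every voxel.  The
    Hessian is computed with Gaussian derivative filters at scale ``sigma``
    (reflective boundaries) and normalized by σ².
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    H = np.empty(volume.shape + (3, 3), dtype=np.float64)
    for (i, j), order in _HESSIAN_ORDERS.items():
        d = _gaussian_derivative(volume, sigma, order)
        d *= sigma**2  # scale normalization
        H[..., i, j] = d
        if i != j:
            H[..., j, i] = d
    eig = np.linalg.eigvalsh(H)  # ascending by value
    order_idx = np.argsort(np.abs(eig), axis=-1)
    return np.take_along_axis(eig, order_idx, axis=-1)


def _single_scale(volume: np.ndarray, sigma: float, params: VesselnessParams) -> np.ndarray:
    eig = hessian_eigenvalues(volume, sigma)
    l1, l2, l3 = eig[..., 0], eig[..., 1], eig[..., 2]
    if params.polarity == "dark_tubes":
        sign_ok = (l2 > 0) & (l3 > 0)
    else:
        sign_ok = (l2 < 0) & (l3 < 0)
    a2, a3 = np.abs(l2), np.abs(l3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ra2 = np.where(a3 > 0, (a2 / np.where(a3 > 0, a3, 1.0)) ** 2, 0.0)
        prod = a2 * a3
        rb2 = np.where(prod > 0, l1**2 / np.where(prod > 0, prod, 1.0), 0.0)
    s2 = l1**2 + l2**2 + l3**2
    c = params.c
    if c is None:
        max_s = float(np.sqrt(s2.max()))
        c = max_s / 2.0 if max_s > 0 else 1.0
    v = (
        (1.0 - np.exp(-ra2 / (2.0 * params.alpha**2)))
        * np.exp(-rb2 / (2.0 * params.beta**2))
        * (1.0 - np.exp(-s2 / (2.0 * c**2)))
    )
    v = np.where(sign_ok, v, 0.0)
    v[s2 == 0] = 0.0
    return v


def frangi_vesselness(
    volume: np.ndarray, params: VesselnessParams | None = None
) -> np.ndarray:
    """Vesselness in [0, 1]: maximum single-scale Frangi response."""
    params = params or VesselnessParams()
    volume = np.asarray(volume, dtype=np.float64)
    out = np.zeros(volume.shape, dtype=np.float64)
    for sigma in params.scales:
        np.maximum(out, _single_scale(volume, sigma, params), out=out)
    return out
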