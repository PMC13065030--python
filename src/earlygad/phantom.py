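"""Deterministic 3-D brain phantom: parcellation labels and T1 volumes.

The phantom stands in for a parcellated patient scan.  It is built from
analytic shapes on a voxel grid:

* a cerebrum sphere whose outer shell is cortex, subdivided into four lobes
  per hemisphere by angular sectors, with white matter inside;
* a central ventricle (CSF) with two choroid-plexus blobs attached to its
  walls;
* left/right basal-ganglia blobs, each threaded by several thin tubes
  (radius ~1 voxel, varied orientations) that are the ground-truth
  perivascular spaces;
* a separate cerebellum sphere (cortex shell + white-matter core).

Geometry is mirror-symmetric about the mid-sagittal plane (axis 0), so
left/right structures are exact reflections of each other.  Axis
convention: 0-based voxel indices, RAS+ world axes, left = lower
first-axis index.

From the labels, :func:`render_t1_pair` produces pre/post-contrast
quantitative T1 maps (ms) and T1-weighted images.  Post-contrast T1 is the
pre-contrast tissue value minus a per-region enhancement magnitude, so the
ground-truth ΔT1 of every voxel is known exactly.  The pre-contrast tissue
T1 values are 3T-plausible placeholders (only ΔT1 is quantified
downstream); T1-weighted intensity is a monotone decreasing function of T1
(∝ 1/T1), which makes CSF-filled spaces (ventricle, PVS) dark, as on real
T1-weighted images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------- labels

LABEL_BACKGROUND = 0

#: label code -> structure name (18 foreground structures)
DEFAULT_CODEBOOK: dict[int, str] = {
    1: "frontal_cortex_L",
    2: "frontal_cortex_R",
    3: "parietal_cortex_L",
    4: "parietal_cortex_R",
    5: "temporal_cortex_L",
    6: "temporal_cortex_R",
    7: "occipital_cortex_L",
    8: "occipital_cortex_R",
    9: "cerebral_white_matter_L",
    10: "cerebral_white_matter_R",
    11: "cerebellar_cortex",
    12: "cerebellar_white_matter",
    13: "basal_ganglia_L",
    14: "basal_ganglia_R",
    15: "ventricle",
    16: "choroid_plexus",
    17: "pvs_L",
    18: "pvs_R",
}

#: region-group name -> member structure names (used for enhancement maps
#: and regional summaries)
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "cerebral_cortex": (
        "frontal_cortex_L", "frontal_cortex_R",
        "parietal_cortex_L", "parietal_cortex_R",
        "temporal_cortex_L", "temporal_cortex_R",
        "occipital_cortex_L", "occipital_cortex_R",
    ),
    "frontal_cortex": ("frontal_cortex_L", "frontal_cortex_R"),
    "parietal_cortex": ("parietal_cortex_L", "parietal_cortex_R"),
    "temporal_cortex": ("temporal_cortex_L", "temporal_cortex_R"),
    "occipital_cortex": ("occipital_cortex_L", "occipital_cortex_R"),
    "cerebral_white_matter": (
        "cerebral_white_matter_L", "cerebral_white_matter_R",
    ),
    "cerebellar_cortex": ("cerebellar_cortex",),
    "cerebellar_white_matter": ("cerebellar_white_matter",),
    "basal_ganglia": ("basal_ganglia_L", "basal_ganglia_R"),
    "bg_pvs": ("pvs_L", "pvs_R"),
    "choroid_plexus": ("choroid_plexus",),
    "ventricle": ("ventricle",),
}

#: pre-contrast tissue T1 (ms), 3T-plausible placeholders
DEFAULT_PRE_T1: dict[str, float] = {
    "frontal_cortex_L": 1400.0, "frontal_cortex_R": 1400.0,
    "parietal_cortex_L": 1400.0, "parietal_cortex_R": 1400.0,
    "temporal_cortex_L": 1400.0, "temporal_cortex_R": 1400.0,
    "occipital_cortex_L": 1400.0, "occipital_cortex_R": 1400.0,
    "cerebral_white_matter_L": 850.0, "cerebral_white_matter_R": 850.0,
    "cerebellar_cortex": 1350.0, "cerebellar_white_matter": 850.0,
    "basal_ganglia_L": 1300.0, "basal_ganglia_R": 1300.0,
    "ventricle": 4000.0, "choroid_plexus": 2200.0,
    "pvs_L": 4000.0, "pvs_R": 4000.0,
}


@dataclass
class LabelVolume:
    """Integer parcellation on a regular grid."""

    grid: np.ndarray  # 3-D int array
    voxel_size: tuple[float, float, float]
    codebook: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CODEBOOK))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3-D")

    @property
    def names(self) -> dict[str, int]:
        return {v: k for k, v in self.codebook.items()}

    def labels_for(self, name: str) -> tuple[int, ...]:
        """Label codes for a structure name or region-group name."""
        names = self.names
        if name in names:
            return (names[name],)
        if name in REGION_GROUPS:
            return tuple(names[m] for m in REGION_GROUPS[name] if m in names)
        raise KeyError(f"unknown region or structure name: {name!r}")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of a structure or region group."""
        return np.isin(self.grid, self.labels_for(name))

    def foreground(self) -> np.ndarray:
        return self.grid != LABEL_BACKGROUND


@dataclass(frozen=True)
class PhantomGeometry:
    """Structure positions and sizes as fractions of the grid extent.

    The tube radius is in voxels (not scaled with the grid) so that the
    PVS calibre stays in the 1-2 voxel regime the vesselness scales target.
    """

    cerebrum_radius: float = 0.30
    cerebrum_z_offset: float = 0.10
    cortex_shell: float = 0.05
    ventricle_semiaxes: tuple[float, float, float] = (0.08, 0.09, 0.05)
    cp_radius: float = 0.04
    cp_center: tuple[float, float, float] = (0.05, -0.09, 0.0)  # ± in x
    bg_center_x: float = 0.18
    bg_semiaxes: tuple[float, float, float] = (0.055, 0.09, 0.09)
    n_tubes: int = 3
    tube_radius_vox: float = 1.1
    cerebellum_center: tuple[float, float, float] = (0.0, -0.28, -0.38)
    cerebellum_radius: float = 0.14

    min_grid: int = 48


def _coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def _tube_mask(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray,
    center: np.ndarray, direction: np.ndarray,
    radius: float, half_length: float,
) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    rx, ry, rz = X - center[0], Y - center[1], Z - center[2]
    t = rx * d[0] + ry * d[1] + rz * d[2]
    dist2 = (rx - t * d[0]) ** 2 + (ry - t * d[1]) ** 2 + (rz - t * d[2]) ** 2
    return (dist2 <= radius**2) & (np.abs(t) <= half_length)


def build_label_volume(
    shape: tuple[int, int, int] = (128, 128, 128),
    voxel_size: float | tuple[float, float, float] = 1.5,
    geometry: PhantomGeometry | None = None,
) -> LabelVolume:
    """Construct the phantom parcellation.

    Grids smaller than ``geometry.min_grid`` along any axis (or with an odd
    first axis, which would put voxels exactly on the mid-sagittal plane)
    are rejected.
    """
    geom = geometry or PhantomGeometry()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must have three axes")
    if min(shape) < geom.min_grid:
        raise ValueError(
            f"grid {shape} too small to contain all structures "
            f"(minimum {geom.min_grid} per axis)"
        )
    if shape[0] % 2 != 0:
        raise ValueError("first axis must be even so no voxel lies on the midplane")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    if min(voxel_size) <= 0:
        raise ValueError("voxel size must be positive")

    N = min(shape)
    cx, cy, cz = ((s - 1) / 2.0 for s in shape)
    X, Y, Z = _coords(shape)
    grid = np.zeros(shape, dtype=np.int16)
    names = {v: k for k, v in DEFAULT_CODEBOOK.items()}
    left = X < cx  # strictly left of the mid-sagittal plane

    # --- cerebrum: cortex shell split into lobes, WM core
    ccz = cz + geom.cerebrum_z_offset * N
    r_cer = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - ccz) ** 2)
    R = geom.cerebrum_radius * N
    shell_t = geom.cortex_shell * N
    cortex = (r_cer <= R) & (r_cer > R - shell_t)
    wm = r_cer <= R - shell_t

    # lobes by angular sector in the sagittal (y, z) plane:
    # frontal = anterior-superior, parietal = posterior-superior,
    # occipital = posterior-inferior, temporal = anterior-inferior
    theta = np.degrees(np.arctan2(Z - ccz, Y - cy)) % 360.0
    sectors = {
        "frontal_cortex": (0.0, 90.0),
        "parietal_cortex": (90.0, 180.0),
        "occipital_cortex": (180.0, 270.0),
        "temporal_cortex": (270.0, 360.0),
    }
    for lobe, (lo, hi) in sectors.items():
        in_sector = cortex & (theta >= lo) & (theta < hi)
        grid[in_sector & left] = names[f"{lobe}_L"]
        grid[in_sector & ~left] = names[f"{lobe}_R"]
    grid[wm & left] = names["cerebral_white_matter_L"]
    grid[wm & ~left] = names["cerebral_white_matter_R"]

    # --- basal ganglia blobs with PVS tubes
    bg_masks = {}
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        bcx = cx + sgn * geom.bg_center_x * N
        ax, ay, az = (s * N for s in geom.bg_semiaxes)
        bg = (
            ((X - bcx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - ccz) / az) ** 2
        ) <= 1.0
        grid[bg] = names[f"basal_ganglia_{side}"]
        bg_masks[side] = (bg, np.array([bcx, cy, ccz]))

    # --- ventricle and choroid plexus
    vax, vay, vaz = (s * N for s in geom.ventricle_semiaxes)
    vent = (
        ((X - cx) / vax) ** 2 + ((Y - cy) / vay) ** 2 + ((Z - ccz) / vaz) ** 2
    ) <= 1.0
    grid[vent] = names["ventricle"]
    for sgn in (-1.0, 1.0):
        ox, oy, oz = geom.cp_center
        center = np.array([cx + sgn * ox * N, cy + oy * N, ccz + oz * N])
        cp = (
            (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        ) <= (geom.cp_radius * N) ** 2
        grid[cp] = names["choroid_plexus"]

    # --- PVS tubes, painted last so they survive inside the BG blobs;
    # directions mirrored between hemispheres to keep exact symmetry
    base_dirs = [
        np.array([0.0, 0.0, 1.0]),
        np.array([0.0, 1.0, 1.0]),
        np.array([1.0, 1.0, 0.0]),
        np.array([1.0, 0.0, 1.0]),
        np.array([0.0, 1.0, 0.0]),
    ]
    half_len = 0.8 * geom.bg_semiaxes[1] * N
    from scipy.ndimage import binary_erosion

    for side, sgn in (("L", -1.0), ("R", 1.0)):
        bg, bcenter = bg_masks[side]
        # tubes stay one voxel clear of the blob surface
        interior = binary_erosion(bg)
        for k in range(geom.n_tubes):
            d = base_dirs[k % len(base_dirs)].copy()
            d[0] *= sgn  # mirror the x component
            # offset tubes off-center so they do not all intersect
            offset = np.array([0.0, 0.0, 0.0])
            if k > 0:
                offset[0] = sgn * (k - geom.n_tubes / 2.0) * 1.5
            tube = _tube_mask(
                X, Y, Z, bcenter + offset, d, geom.tube_radius_vox, half_len
            )
            grid[tube & interior] = names[f"pvs_{side}"]

    # --- cerebellum: cortex shell + WM core
    ox, oy, oz = geom.cerebellum_center
    ccb = np.array([cx + ox * N, cy + oy * N, cz + oz * N + geom.cerebrum_z_offset * N])
    r_cb = np.sqrt((X - ccb[0]) ** 2 + (Y - ccb[1]) ** 2 + (Z - ccb[2]) ** 2)
    Rcb = geom.cerebellum_radius * N
    cb_shell = geom.cortex_shell * N
    grid[(r_cb <= Rcb) & (r_cb > Rcb - cb_shell)] = names["cerebellar_cortex"]
    grid[r_cb <= Rcb - cb_shell] = names["cerebellar_white_matter"]

    vol = LabelVolume(grid=grid, voxel_size=tuple(voxel_size))
    present = set(np.unique(grid)) - {LABEL_BACKGROUND}
    missing = set(DEFAULT_CODEBOOK) - present
    if missing:
        raise ValueError(
            "grid too small: structures with zero volume: "
            + ", ".join(DEFAULT_CODEBOOK[m] for m in sorted(missing))
        )
    return vol


# ------------------------------------------------------------- rendering


def enhancement_to_per_label(
    labels: LabelVolume, enhancement: dict[str, float]
) -> dict[int, float]:
    """Expand a region/structure-keyed enhancement map to label codes.

    Keys may be structure names or region-group names; later keys override
    earlier ones label-by-label, so a group value can be refined by a more
    specific entry given afterwards.  Unknown keys are rejected.
    """
    per_label: dict[int, float] = {}
    for key, value in enhancement.items():
        for code in labels.labels_for(key):  # raises KeyError on unknown
            per_label[code] = float(value)
    return per_label


def render_t1_pair(
    labels: LabelVolume,
    enhancement: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    pre_t1: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Render pre/post-contrast T1 maps (ms) and T1-weighted images.

    ``enhancement`` maps region or structure names to the T1 *reduction*
    magnitude in ms (positive number = enhancement; the resulting ΔT1 is
    its negative).  Gaussian voxel noise with SD ``noise_sd`` (ms) is added
    independently to the pre and post maps; with ``noise_sd = 0`` the maps
    are exact.  Returns a dict with keys ``t1_pre``, ``t1_post``,
    ``t1w_pre``, ``t1w_post``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    enhancement = enhancement or {}
    pre_vals = dict(DEFAULT_PRE_T1)
    if pre_t1:
        pre_vals.update(pre_t1)
    per_label = enhancement_to_per_label(labels, enhancement)

    grid = labels.grid
    t1_pre = np.zeros(grid.shape, dtype=np.float64)
    t1_post = np.zeros(grid.shape, dtype=np.float64)
    names = labels.names
    for name, base in pre_vals.items():
        code = names.get(name)
        if code is None:
            continue
        m = grid == code
        t1_pre[m] = base
        t1_post[m] = base - per_label.get(code, 0.0)

    fg = labels.foreground()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        t1_pre[fg] += noise_sd * rng.standard_normal(int(fg.sum()))
        t1_post[fg] += noise_sd * rng.standard_normal(int(fg.sum()))

    return {
        "t1_pre": t1_pre,
        "t1_post": t1_post,
        "t1w_pre": t1w_from_t1(t1_pre, fg),
        "t1w_post": t1w_from_t1(t1_post, fg),
    }


def t1w_from_t1(t1: np.ndarray, foreground: np.ndarray) -> np.ndarray:
    """Synthesize a T1-weighted image as a monotone decreasing map of T1.

    Intensity = 1000 * 800 / T1 (a.u., clipped to [0, 1000]); long-T1
    tissue (CSF, PVS) comes out dark, short-T1 tissue bright, which is the
    contrast property consumed downstream.  Background stays 0.
    """
    out = np.zeros(t1.shape, dtype=np.float64)
    safe = np.clip(t1[foreground], 1.0, None)
    out[foreground] = np.clip(1000.0 * 800.0 / safe, 0.0, 1000.0)
    return out
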