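"""NIfTI and sidecar file I/O."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import LabelVolume


def write_nifti(path, grid: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a volume as single-file NIfTI-1 with the voxel size in the
    affine (RAS+, origin at voxel 0)."""
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    affine = np.diag([*vs, 1.0])
    img = nib.Nifti1Image(np.asarray(grid), affine)
    img.header.set_zooms(tuple(vs))
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 volume; returns (array, voxel_size).  Malformed or
    non-NIfTI files are rejected with a clear error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_label_volume(path, labels: LabelVolume) -> None:
    """Label grid as NIfTI plus a JSON codebook sidecar (<path>.labels.json)."""
    write_nifti(path, labels.grid.astype(np.int16), labels.voxel_size)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii[.gz]
    with open(f"{sidecar}.labels.json", "w") as fh:
        json.dump({str(k): v for k, v in labels.codebook.items()}, fh, indent=1)


def read_label_volume(path) -> LabelVolume:
    grid, vs = read_nifti(path)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    codebook_path = Path(f"{sidecar}.labels.json")
    if codebook_path.exists():
        with open(codebook_path) as fh:
            codebook = {int(k): v for k, v in json.load(fh).items()}
    else:
        from .phantom import DEFAULT_CODEBOOK

        codebook = dict(DEFAULT_CODEBOOK)
    return LabelVolume(grid=grid.astype(np.int16), voxel_size=vs, codebook=codebook)
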