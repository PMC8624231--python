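"""NIfTI input/output backed by nibabel.

Round-trips data, spacing, and affine losslessly for floating-point image
volumes and integer label maps (.nii and .nii.gz).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .core import LabelMap, Volume3D

__all__ = ["read_volume", "write_volume", "read_labels", "write_labels",
           "read_channels", "write_channels"]


def _load(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several parse error types
        raise ValueError(f"failed to read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D (or 4D multi-modality) volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=np.float64)


def read_volume(path) -> Volume3D:
    """Read a scalar 3D volume (4D inputs are rejected here; split channels upstream)."""
    data, spacing, affine = _load(path)
    if data.ndim == 4:
        raise ValueError(f"{path} is 4D; read channels individually (e.g. data[..., c])")
    return Volume3D(np.asarray(data, dtype=np.float64), spacing=spacing, affine=affine)


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_channels(path) -> list:
    """Read a 3D volume as a one-element list, or a 4D multi-modality volume
    as one Volume3D per channel (last axis), sharing geometry."""
    data, spacing, affine = _load(path)
    if data.ndim == 3:
        return [Volume3D(np.asarray(data, dtype=np.float64), spacing=spacing, affine=affine)]
    return [
        Volume3D(np.asarray(data[..., c], dtype=np.float64), spacing=spacing, affine=affine)
        for c in range(data.shape[-1])
    ]


def write_channels(vols, path) -> None:
    """Write one volume as 3D NIfTI, several as a 4D multi-modality NIfTI."""
    vols = list(vols)
    if len(vols) == 1:
        write_volume(vols[0], path)
        return
    stacked = np.stack([v.data for v in vols], axis=-1)
    img = nib.Nifti1Image(stacked.astype(np.float64), vols[0].affine)
    img.header.set_zooms(tuple(vols[0].spacing) + (1.0,))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    """Read an integer label map, preserving integer semantics."""
    data, spacing, affine = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: label maps must be 3D")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"{path}: non-integer values in label map")
        data = rounded
    return LabelMap(data.astype(np.int16), spacing=spacing, affine=affine)


def write_labels(lmap: LabelMap, path) -> None:
    img = nib.Nifti1Image(lmap.labels.astype(np.int16), lmap.affine)
    img.header.set_zooms(lmap.spacing)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
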