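"""Core in-memory containers shared by every processing stage.

A :class:`Volume3D` is a single-channel scalar volume with voxel spacing and
an affine; a :class:`LabelMap` is an integer volume in the BraTS label
dialect (0 background, 1 necrotic/non-enhancing core, 2 edema, 4 enhancing
tumor) from which the three nested evaluation regions are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Labels admitted by the BraTS dialect.
VALID_LABELS = frozenset({0, 1, 2, 4})

#: Label sets defining the nested evaluation regions.
WHOLE_LABELS = (1, 2, 4)
CORE_LABELS = (1, 4)
ENHANCING_LABELS = (4,)


def _default_affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class Volume3D:
    """A 3D scalar image plus geometry metadata.

    Parameters
    ----------
    data:
        3D floating-point array of intensities (arbitrary units).
    spacing:
        Physical size of a voxel in mm along each axis; strictly positive.
    affine:
        4x4 voxel-to-world matrix. Defaults to a diagonal matrix built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D data must be finite everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume carrying ``data`` with this volume's geometry."""
        return Volume3D(np.asarray(data), spacing=self.spacing, affine=self.affine.copy())

    def foreground_mask(self) -> np.ndarray:
        """Strictly-positive voxels — the default mask for skull-stripped data."""
        return self.data > 0

    def copy(self) -> "Volume3D":
        return self.with_data(self.data.copy())


@dataclass
class LabelMap:
    """Integer segmentation volume in the BraTS label dialect."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap requires an integer-valued array")
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    def validate_labels(self) -> None:
        """Raise if any voxel carries a label outside the dialect."""
        present = set(np.unique(self.labels).tolist())
        unknown = sorted(present - VALID_LABELS)
        if unknown:
            raise ValueError(f"unknown label values: {unknown} (expected subset of {sorted(VALID_LABELS)})")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def whole(self) -> np.ndarray:
        return np.isin(self.labels, WHOLE_LABELS)

    @property
    def core(self) -> np.ndarray:
        return np.isin(self.labels, CORE_LABELS)

    @property
    def enhancing(self) -> np.ndarray:
        return np.isin(self.labels, ENHANCING_LABELS)
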