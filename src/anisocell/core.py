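"""Shared containers and conventions.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)``; the organ's long axis runs along z.
* World coordinates are voxel index times spacing, in the same (z, y, x)
  order, in micrometres; voxel ``i`` occupies the half-open box
  ``[i * spacing, (i + 1) * spacing)`` and its centre is at
  ``(i + 0.5) * spacing``.
* Label 0 is background; cell labels are positive integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical per-cell CSV schema (one row per cell).
CELL_CSV_COLUMNS = [
    "cell_id",
    "replicate_id",
    "time_hai",
    "position",
    "layer",
    "volume_um3",
    "len_long_um",
    "len_rad_um",
    "len_circ_um",
    "radial_dist_um",
    "axis_t",
]


@dataclass
class LabeledVolume:
    """A 3D integer label grid with physical voxel spacing.

    Parameters
    ----------
    labels : ndarray of int, shape (nz, ny, nx)
        0 is background, positive integers are cells.
    spacing : tuple of float
        Voxel edge length in µm per axis, (z, y, x) order.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        """Sorted array of nonzero labels present in the grid."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


def as_label_array(volume) -> np.ndarray:
    """Accept a LabeledVolume or a bare integer array; return the array."""
    if isinstance(volume, LabeledVolume):
        return volume.labels
    arr = np.asarray(volume)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("labels must be integer-valued")
    return arr
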