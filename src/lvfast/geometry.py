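"""Voxel geometry and the 4D cine container.

Conventions used throughout the package:

* slice index 0 is the most basal acquired slice, increasing toward the apex;
* phase index 0 is the first reconstructed phase (nominal end diastole) and
  phases are treated as cyclic wherever adjacency matters;
* pixel coordinates are 0-based ``(row, col)``;
* areas are carried in pixels internally and converted to mm²/mL only when
  clinical metrics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGeometry", "CineStack"]

#: minimum stack size for the pipeline: fewer slices cannot bracket a
#: mid-ventricular band, fewer phases make the cyclic jump logic degenerate.
MIN_SLICES = 5
MIN_PHASES = 10


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel geometry of a short-axis stack.

    Parameters
    ----------
    pixel_spacing_row, pixel_spacing_col : float
        In-plane spacing in mm/pixel.
    slice_spacing : float
        Centre-to-centre distance between adjacent slices in mm, i.e. slice
        thickness plus inter-slice gap (typically 10 mm for short-axis cine).
    """

    pixel_spacing_row: float
    pixel_spacing_col: float
    slice_spacing: float

    def __post_init__(self) -> None:
        for name in ("pixel_spacing_row", "pixel_spacing_col", "slice_spacing"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.slice_spacing < max(self.pixel_spacing_row, self.pixel_spacing_col):
            warnings.warn(
                "slice_spacing is smaller than the in-plane pixel spacing; "
                "check the geometry metadata",
                stacklevel=2,
            )

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_row * self.pixel_spacing_col


@dataclass
class CineStack:
    """A 4D short-axis cine stack indexed ``(slice, phase, row, col)``.

    Slices are ordered base→apex, phases by trigger time.  Intensities are in
    arbitrary scanner units and must be finite and non-negative.
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    slice_order: str = field(default="base-to-apex")

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 4:
            raise ValueError(
                f"cine stack must be 4D (slice, phase, row, col), got ndim={arr.ndim}"
            )
        if not np.isfinite(arr).all():
            raise ValueError("cine intensities must be finite")
        if arr.min() < 0:
            raise ValueError("cine intensities must be non-negative")
        if arr.shape[0] < MIN_SLICES:
            raise ValueError(
                f"pipeline requires >= {MIN_SLICES} slices, got {arr.shape[0]}"
            )
        if arr.shape[1] < MIN_PHASES:
            raise ValueError(
                f"pipeline requires >= {MIN_PHASES} phases, got {arr.shape[1]}"
            )
        self.intensities = arr

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_phases(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.intensities.shape

    def frame(self, slice_index: int, phase: int) -> np.ndarray:
        """Return the 2D image at ``(slice_index, phase)``."""
        return self.intensities[slice_index, phase]

    @property
    def middle_slice(self) -> int:
        """Index of the mid-ventricular slice, ``n_slices // 2``."""
        return self.n_slices // 2
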