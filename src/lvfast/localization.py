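"""Initial seed localization and seed propagation.

The mid-ventricular seed is found on the absolute difference image between a
nominally end-diastolic and a nominally end-systolic phase of the middle
slice: the LV is the roundest structure undergoing the most motion, so the
centre of the strongest circle in a circular Hough transform of the
difference image's edge map is a robust blood-pool seed.  Once one frame is
segmented, seeds for neighbouring slices/phases are simply blood-pool
centres of mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle

__all__ = [
    "SeedPoint",
    "SeedingError",
    "difference_image",
    "hough_seed",
    "propagate_seed",
    "default_radius_range",
]

#: reference in-plane spacing (mm) at which the default Hough radius range
#: of 8–40 px corresponds to LV radii of roughly 1–6 cm
_REFERENCE_SPACING_MM = 1.4
_DEFAULT_RADIUS_RANGE_PX = (8, 40)
#: minimum normalised accumulator value accepted as a circle
_ACCUMULATOR_FLOOR = 0.25
#: relative accumulator difference below which peaks are treated as tied
_TIE_RTOL = 1e-3


class SeedingError(RuntimeError):
    """Raised when no usable seed can be located."""


@dataclass(frozen=True)
class SeedPoint:
    """A segmentation seed in pixel coordinates, with provenance."""

    row: int
    col: int
    slice: Optional[int] = None
    phase: Optional[int] = None
    origin: str = "hough"

    def as_tuple(self) -> tuple[int, int]:
        return (self.row, self.col)


def default_radius_range(pixel_spacing_mm: float) -> tuple[int, int]:
    """Hough radius range in pixels, scaled from 8–40 px at 1.4 mm spacing."""
    lo, hi = _DEFAULT_RADIUS_RANGE_PX
    scale = _REFERENCE_SPACING_MM / pixel_spacing_mm
    return (max(2, round(lo * scale)), max(3, round(hi * scale)))


def difference_image(stack, slice_index: int, phase_a: int, phase_b: int) -> np.ndarray:
    """Absolute per-pixel difference of two phases of one slice."""
    n_phases = stack.n_phases
    for p in (phase_a, phase_b):
        if not 0 <= p < n_phases:
            raise IndexError(f"phase index {p} out of range [0, {n_phases})")
    a = stack.frame(slice_index, phase_a)
    b = stack.frame(slice_index, phase_b)
    return np.abs(a - b)


def hough_seed(
    diff: np.ndarray,
    radius_range: tuple[int, int] = _DEFAULT_RADIUS_RANGE_PX,
) -> SeedPoint:
    """Centre of the strongest circle in the difference image's edge map.

    Edges are gradient-magnitude (Sobel) pixels above the Otsu level.  The
    circular Hough accumulator is searched over ``radius_range`` (inclusive);
    ties within a small relative tolerance are broken deterministically by
    smallest radius, then smallest row, then smallest column.
    """
    diff = np.asarray(diff, dtype=float)
    if diff.size == 0 or not np.any(diff > 0):
        raise SeedingError("no moving round object found (difference image is zero)")
    grad = sobel(diff)
    try:
        level = threshold_otsu(grad)
    except ValueError:  # constant gradient image
        raise SeedingError("no moving round object found (flat difference image)")
    edges = grad > level
    if not edges.any():
        raise SeedingError("no moving round object found (no edges)")

    r_lo, r_hi = radius_range
    radii = np.arange(int(r_lo), int(r_hi) + 1)
    acc = hough_circle(edges, radii, normalize=True)
    peak = float(acc.max())
    if peak < _ACCUMULATOR_FLOOR:
        raise SeedingError(
            f"no moving round object found (accumulator peak {peak:.3f})"
        )
    tied = np.argwhere(acc >= peak * (1.0 - _TIE_RTOL))
    # lexicographic (radius, row, col) — argwhere rows are already sorted
    r_idx, row, col = tied[0]
    return SeedPoint(row=int(row), col=int(col), origin="hough")


def propagate_seed(prev_mask: np.ndarray) -> SeedPoint:
    """Seed for an adjacent frame: centre of mass of the previous blood pool.

    The centroid is rounded to integer pixels; if it falls clear of the mask
    (crescent-shaped pools whose centre of mass lies in the gap) it is
    snapped to the nearest mask pixel.  A centroid pixel touching the mask
    (within its 8-neighbourhood) is kept as-is.
    """
    prev_mask = np.asarray(prev_mask, dtype=bool)
    if not prev_mask.any():
        raise SeedingError("cannot propagate seed from an empty mask")
    rr, cc = np.nonzero(prev_mask)
    row = int(round(float(rr.mean())))
    col = int(round(float(cc.mean())))
    if not prev_mask[row, col]:
        d2 = (rr - row) ** 2 + (cc - col) ** 2
        k = int(np.argmin(d2))
        if d2[k] > 2:  # not even diagonally adjacent: snap into the pool
            row, col = int(rr[k]), int(cc[k])
    return SeedPoint(row=row, col=col, origin="propagated-from-centroid")
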