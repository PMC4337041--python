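"""Iterative decreasing-threshold region growing for a single 2D frame.

From a blood-pool seed, the region at threshold fraction ``t`` is the set of
pixels 4-connected to the seed with intensity at least ``t * I0``, where
``I0`` is the mean intensity of the seed's 3x3 neighbourhood.  ``t`` is
lowered stepwise; growth stops either when the newly added pixels' mean
intensity drops below the myocardium-plateau fraction of ``I0`` (the region
has reached the dark wall) or when the region area inflates by more than
``leak_area_ratio`` in a single step (the region has leaked through a narrow
bright bridge into the atrium, aorta or right ventricle).  In the second
case the pre-leak region is returned and the frame is flagged ``leaked``.

The returned mask is hole-filled: papillary muscles enclosed by blood are
counted as cavity, matching clinical convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .localization import SeedPoint

__all__ = ["GrowConfig", "FrameMask", "GrowthError", "grow_frame"]

_STRUCTURE_4 = ndi.generate_binary_structure(2, 1)


class GrowthError(RuntimeError):
    """Raised when region growing cannot start from the given seed."""


@dataclass(frozen=True)
class GrowConfig:
    """Tunable constants of the growth engine.

    ``threshold_fraction_start`` and ``threshold_step`` are fractions of the
    seed-neighbourhood intensity ``I0``; ``leak_area_ratio`` is the maximum
    tolerated single-step area growth factor; ``plateau_fraction`` is the
    fraction of ``I0`` below which newly added pixels are considered
    myocardium rather than blood.
    """

    threshold_fraction_start: float = 0.95
    threshold_step: float = 0.05
    leak_area_ratio: float = 2.0
    max_iterations: int = 50
    plateau_fraction: float = 0.6
    #: a growth step only counts as a leak when the added pixels are dimmer
    #: than this fraction of I0: leaks cross partial-volume bridges into
    #: structures of different intensity, whereas consolidation of the noisy
    #: blood pool adds pixels near blood intensity however fast it grows
    leak_intensity_fraction: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.threshold_step < self.threshold_fraction_start <= 1:
            raise ValueError("require 0 < step < start <= 1")
        if self.leak_area_ratio <= 1:
            raise ValueError("leak_area_ratio must exceed 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FrameMask:
    """Result of growing one frame."""

    mask: np.ndarray  # bool 2D, 4-connected, seed-containing, hole-filled
    area_px: int
    centroid: tuple[float, float]  # (row, col) mean of mask pixels
    threshold_used: float  # absolute intensity of the accepted threshold
    leaked: bool
    #: (threshold fraction, region area) per accepted iteration, for debugging
    trace: list[tuple[float, int]] = field(default_factory=list)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "FrameMask":
        return cls(
            mask=np.zeros(shape, dtype=bool),
            area_px=0,
            centroid=(float("nan"), float("nan")),
            threshold_used=float("nan"),
            leaked=False,
        )


def _seed_neighbourhood_mean(image: np.ndarray, row: int, col: int) -> float:
    r0, r1 = max(0, row - 1), min(image.shape[0], row + 2)
    c0, c1 = max(0, col - 1), min(image.shape[1], col + 2)
    return float(image[r0:r1, c0:c1].mean())


def grow_frame(image: np.ndarray, seed, cfg: Optional[GrowConfig] = None) -> FrameMask:
    """Segment the blood pool around ``seed`` in one 2D frame.

    ``seed`` may be a :class:`~lvfast.localization.SeedPoint` or an
    ``(row, col)`` pair.  Raises :class:`GrowthError` when the seed is not in
    bright blood (non-positive neighbourhood intensity, or a neighbourhood
    darker than the image's Otsu level, i.e. seeded on background or
    myocardium).
    """
    cfg = cfg or GrowConfig()
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image must be finite")
    if isinstance(seed, SeedPoint):
        row, col = seed.row, seed.col
    else:
        row, col = int(seed[0]), int(seed[1])
    if not (0 <= row < image.shape[0] and 0 <= col < image.shape[1]):
        raise ValueError(f"seed ({row}, {col}) outside image {image.shape}")

    i0 = _seed_neighbourhood_mean(image, row, col)
    if i0 <= 0:
        raise GrowthError("seed not in blood pool (non-positive intensity)")
    if image.max() > image.min():
        try:
            if i0 < threshold_otsu(image):
                raise GrowthError("seed not in blood pool (dark neighbourhood)")
        except ValueError:
            pass

    best_region: Optional[np.ndarray] = None
    best_area = 0
    best_fraction = float("nan")
    leaked = False
    trace: list[tuple[float, int]] = []

    t = cfg.threshold_fraction_start
    for _ in range(cfg.max_iterations):
        if t <= 0:
            break
        thr = t * i0
        above = image >= thr
        if above[row, col]:
            labels, _ = ndi.label(above, structure=_STRUCTURE_4)
            region = labels == labels[row, col]
            area = int(region.sum())
            if best_region is not None and best_area > 0:
                added = region & ~best_region
                n_added = int(added.sum())
                if n_added:
                    added_mean = float(image[added].mean())
                    if added_mean < cfg.plateau_fraction * i0:
                        break  # reached the myocardial plateau
                    if (
                        area > cfg.leak_area_ratio * best_area
                        and added_mean < cfg.leak_intensity_fraction * i0
                    ):
                        leaked = True
                        break  # leaked through a bridge; keep pre-leak region
            best_region, best_area, best_fraction = region, area, t
            trace.append((t, area))
        t -= cfg.threshold_step

    if best_region is None:
        raise GrowthError("seed not in blood pool (never above threshold)")

    mask = ndi.binary_fill_holes(best_region)
    rr, cc = np.nonzero(mask)
    return FrameMask(
        mask=mask,
        area_px=int(mask.sum()),
        centroid=(float(rr.mean()), float(cc.mean())),
        threshold_used=best_fraction * i0,
        leaked=leaked,
        trace=trace,
    )
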