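"""Spatiotemporal continuity: the Step-1 sweep and jump classification.

Away from the extremes of the stack, per-slice LV areas vary smoothly over
both slice position and cardiac phase.  The surface ``A(p, s)`` of segmented
areas therefore exposes where the growth engine failed: a frame whose area
ratio against its already-accepted neighbour exceeds ``J_max`` or whose
blood-pool centre jumps by more than ``D_max`` pixels is a "jump image",
and everything at and beyond the first jump slice of a phase is treated as
unreliable.  The sweep is anchored at the mid-ventricular slice — the
easiest, most trusted segmentation — and moves outward toward apex and base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import CineStack
from .localization import (
    SeedingError,
    SeedPoint,
    default_radius_range,
    difference_image,
    hough_seed,
    propagate_seed,
)
from .region_grow import FrameMask, GrowConfig, GrowthError, grow_frame

__all__ = [
    "AreaMap",
    "JumpParams",
    "SegResult",
    "jump_ratio",
    "center_displacement",
    "classify_jumps",
    "run_step1",
]


@dataclass
class AreaMap:
    """The ``A(p, s)`` surface: per-(phase, slice) areas and centroids.

    ``first_apical_jump_slice`` / ``first_basal_jump_slice`` hold, per phase,
    the index of the first jump slice on each side of the mid-ventricular
    anchor, or ``-1`` where no jump was found on that side.
    """

    area: np.ndarray  # (n_phases, n_slices), pixels
    centroid_row: np.ndarray  # (n_phases, n_slices), NaN where empty
    centroid_col: np.ndarray
    jump: np.ndarray = field(default=None)  # bool, same shape
    first_apical_jump_slice: np.ndarray = field(default=None)  # per phase, -1 = none
    first_basal_jump_slice: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if (self.area < 0).any():
            raise ValueError("areas must be non-negative")
        p, s = self.area.shape
        if self.jump is None:
            self.jump = np.zeros((p, s), dtype=bool)
        if self.first_apical_jump_slice is None:
            self.first_apical_jump_slice = np.full(p, -1, dtype=int)
        if self.first_basal_jump_slice is None:
            self.first_basal_jump_slice = np.full(p, -1, dtype=int)

    @property
    def n_phases(self) -> int:
        return self.area.shape[0]

    @property
    def n_slices(self) -> int:
        return self.area.shape[1]

    def centroid(self, p: int, s: int) -> tuple[float, float]:
        return (float(self.centroid_row[p, s]), float(self.centroid_col[p, s]))


@dataclass(frozen=True)
class JumpParams:
    """Thresholds of the jump rules (area ratio and centre displacement)."""

    j_max: float = 2.5
    d_max: float = 6.0  # pixels
    #: flag a whole slice when the temporal rule fails for at least this
    #: fraction of its phases even though the spatial rule passed
    temporal_wholesale_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.j_max <= 1:
            raise ValueError("j_max must exceed 1")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


@dataclass
class SegResult:
    """Per-(slice, phase) binary masks and growth diagnostics."""

    masks: np.ndarray  # bool, (slice, phase, row, col)
    leaked: np.ndarray  # bool, (slice, phase)
    threshold_used: np.ndarray  # (slice, phase)
    geometry: object = None  # VoxelGeometry of the source stack
    seed: Optional[SeedPoint] = None  # the initial Hough seed

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def n_phases(self) -> int:
        return self.masks.shape[1]


def jump_ratio(a_test: float, a_ref: float) -> float:
    """Area ratio ``J`` of a frame against its reference neighbour.

    A zero-area reference yields ``+inf`` so the comparison is always
    treated as a jump.
    """
    if a_ref == 0:
        return math.inf
    return a_test / a_ref


def center_displacement(
    c_test: tuple[float, float], c_ref: tuple[float, float]
) -> float:
    """Euclidean centre-of-mass displacement ``D`` in pixels.

    An undefined centroid (NaN component, from an empty mask) yields
    ``+inf`` so the comparison is always treated as a jump.
    """
    values = (*c_test, *c_ref)
    if any(v is None or not math.isfinite(v) for v in values):
        return math.inf
    return math.hypot(c_test[0] - c_ref[0], c_test[1] - c_ref[1])


def _violates(amap: AreaMap, params: JumpParams, p: int, s: int, p_ref: int, s_ref: int) -> bool:
    j = jump_ratio(amap.area[p, s], amap.area[p_ref, s_ref])
    d = center_displacement(amap.centroid(p, s), amap.centroid(p_ref, s_ref))
    return j > params.j_max or d > params.d_max


def classify_jumps(amap: AreaMap, params: JumpParams, ms: int) -> AreaMap:
    """Flag jump images by sweeping outward from the mid-ventricular slice.

    For each phase the sweep compares each cell to its already-accepted
    spatial neighbour one slice closer to ``ms``; the first violating slice
    and everything beyond it (toward the apex on one side, toward the base
    on the other) is flagged unreliable.  Temporal adjacency (cyclic over
    the cardiac cycle) corroborates: a slice whose temporal rule fails for
    at least half of its phases is flagged wholesale even where the spatial
    rule passed.

    Raises if the mid-ventricular cell itself is empty at any phase — the
    anchor segmentation failed and nothing downstream can be trusted.
    """
    n_phases, n_slices = amap.area.shape
    if not 0 <= ms < n_slices:
        raise ValueError(f"middle slice {ms} out of range")
    if (amap.area[:, ms] == 0).any():
        raise RuntimeError("mid-ventricular segmentation failed (empty anchor cell)")

    jump = np.zeros((n_phases, n_slices), dtype=bool)
    first_apical = np.full(n_phases, -1, dtype=int)
    first_basal = np.full(n_phases, -1, dtype=int)

    for p in range(n_phases):
        for s in range(ms + 1, n_slices):  # toward the apex
            if _violates(amap, params, p, s, p, s - 1):
                jump[p, s:] = True
                first_apical[p] = s
                break
        for s in range(ms - 1, -1, -1):  # toward the base
            if _violates(amap, params, p, s, p, s + 1):
                jump[p, : s + 1] = True
                first_basal[p] = s
                break

    # temporal corroboration: cyclic phase adjacency, evaluated per slice
    for s in range(n_slices):
        if s == ms:
            continue  # the anchor is trusted
        fails = sum(
            _violates(amap, params, p, s, (p - 1) % n_phases, s)
            for p in range(n_phases)
        )
        if fails >= params.temporal_wholesale_fraction * n_phases:
            if s > ms:
                jump[:, s:] = True
                first_apical = np.where(
                    (first_apical == -1) | (first_apical > s), s, first_apical
                )
            else:
                jump[:, : s + 1] = True
                first_basal = np.where(
                    (first_basal == -1) | (first_basal < s), s, first_basal
                )

    return replace(
        amap,
        jump=jump,
        first_apical_jump_slice=first_apical,
        first_basal_jump_slice=first_basal,
    )


def run_step1(
    stack: CineStack,
    cfg: Optional[GrowConfig] = None,
    seed_phases: tuple[int, int] = (0, 7),
    radius_range: Optional[tuple[int, int]] = None,
) -> tuple[SegResult, AreaMap]:
    """Segment every frame of the stack, anchored at the middle slice.

    The initial seed comes from the Hough transform of the difference image
    between the two ``seed_phases`` at the middle slice; all phases of the
    middle slice are grown from that seed, then slices are processed outward
    in both directions, each frame seeded by the blood-pool centroid of the
    adjacent completed slice at the same phase.  Every frame is segmented
    even where growth leaks — the continuity stage detects those failures.
    Frames whose seeding or growth fails outright yield empty masks.
    """
    cfg = cfg or GrowConfig()
    ms = stack.middle_slice
    if radius_range is None:
        radius_range = default_radius_range(
            min(stack.geometry.pixel_spacing_row, stack.geometry.pixel_spacing_col)
        )
    pa, pb = seed_phases
    diff = difference_image(stack, ms, pa, pb)
    try:
        seed = hough_seed(diff, radius_range)
    except SeedingError as exc:
        raise SeedingError(
            f"initial localization failed on middle slice {ms}: {exc}"
        ) from exc
    seed = SeedPoint(seed.row, seed.col, slice=ms, phase=pa, origin="hough")

    n_s, n_p = stack.n_slices, stack.n_phases
    shape_2d = stack.intensities.shape[2:]
    frames: list[list[Optional[FrameMask]]] = [
        [None] * n_p for _ in range(n_s)
    ]

    def grow_or_empty(s: int, p: int, sd) -> FrameMask:
        try:
            return grow_frame(stack.frame(s, p), sd, cfg)
        except GrowthError:
            return FrameMask.empty(shape_2d)

    for p in range(n_p):
        frames[ms][p] = grow_or_empty(ms, p, seed)

    for direction in (1, -1):
        s = ms + direction
        while 0 <= s < n_s:
            prev = s - direction
            for p in range(n_p):
                try:
                    sd = propagate_seed(frames[prev][p].mask)
                except SeedingError:
                    frames[s][p] = FrameMask.empty(shape_2d)
                    continue
                frames[s][p] = grow_or_empty(s, p, sd)
            s += direction

    masks = np.zeros((n_s, n_p, *shape_2d), dtype=bool)
    leaked = np.zeros((n_s, n_p), dtype=bool)
    thr = np.full((n_s, n_p), np.nan)
    area = np.zeros((n_p, n_s))
    c_row = np.full((n_p, n_s), np.nan)
    c_col = np.full((n_p, n_s), np.nan)
    for s in range(n_s):
        for p in range(n_p):
            fm = frames[s][p]
            masks[s, p] = fm.mask
            leaked[s, p] = fm.leaked
            thr[s, p] = fm.threshold_used
            area[p, s] = fm.area_px
            c_row[p, s], c_col[p, s] = fm.centroid

    seg = SegResult(
        masks=masks, leaked=leaked, threshold_used=thr,
        geometry=stack.geometry, seed=seed,
    )
    amap = AreaMap(area=area, centroid_row=c_row, centroid_col=c_col)
    return seg, amap
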