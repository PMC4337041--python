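"""Apical estimation and basal detection at the flagged extremes.

Apical jump images are replaced by estimates rather than re-segmented: a
phase-scaled estimate transfers the area from the nearest reliable phase of
the same slice, scaled by the volume ratio of the reliable mid-to-apical
section between the two phases; where no reliable phase exists the area is
extrapolated assuming the cavity tapers like a cone, i.e. the equivalent
circular radius decreases linearly toward the tip.

Basal jump images are interrogated with a polar map: for each 1° ray from
the LV centre, the radius of the first background run of the (smoothed)
mask marks the apparent myocardial border, and the two pixels immediately
beyond it are apparent myocardial points.  Comparing the jump slice's polar
profile with the last reliable slice locates the two angles where the
border abruptly recedes — the myocardial termination points flanking the
outflow tract.  The slice still contains LV only if at least half the
circumference (>= 180°) remains bordered by myocardium and the apparent
myocardial points are within 30% of the reference slice's myocardial
intensity (ruling out atrium or aorta); if so, the cavity is closed by the
straight chord between the two termination points, as a clinician draws the
basal boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from skimage.morphology import closing, disk, opening

from .continuity import AreaMap

__all__ = [
    "ApicalEstimate",
    "PolarMap",
    "Termination",
    "BasalDecision",
    "NoReliablePhaseError",
    "estimate_apical_phase_scaled",
    "estimate_apical_cone",
    "smooth_mask",
    "build_polar_map",
    "find_termination_points",
    "mean_myocardial_intensity",
    "decide_basal",
]

N_ANGULAR_BINS = 360  # 1° angular resolution
RADIAL_STEP_PX = 0.5
#: a radial background run must span at least this many pixels to count as
#: the myocardial border (skips single-pixel noise gaps)
MIN_ZERO_RUN_PX = 2.0

_DISK3 = disk(3)


class NoReliablePhaseError(RuntimeError):
    """No non-jump phase available for phase-scaled apical estimation."""


@dataclass(frozen=True)
class ApicalEstimate:
    """An estimated apical area with its provenance."""

    area_est: float  # pixels
    method: str  # "phase-scaled" or "cone"
    source_phase: Optional[int] = None  # for phase-scaled estimates


@dataclass
class PolarMap:
    """Angle x radius view of a candidate basal mask.

    ``radius_of_first_zero[k]`` is the radius (pixels from ``center``) of the
    first background run of length >= 2 px along the ray at ``k`` degrees;
    ``myo_points[k]`` holds the integer (row, col) coordinates of the two
    pixels immediately beyond that border.  Angle 0 points along +col and
    angles increase toward +row.
    """

    radius_of_first_zero: np.ndarray  # (360,)
    myo_points: np.ndarray  # (360, 2, 2) int
    center: tuple[float, float]


class Termination(NamedTuple):
    """Myocardial termination angles (degrees) and the zero-angle reference."""

    theta1: float
    theta2: float
    zero_angle: float


@dataclass
class BasalDecision:
    """Outcome of interrogating one basal jump image."""

    contains_lv: bool
    termination_angles: Optional[tuple[float, float]]
    myocardial_coverage_deg: float
    intensity_ratio: float
    closed_mask: Optional[np.ndarray]


# --------------------------------------------------------------------------
# apical estimation


def estimate_apical_phase_scaled(
    amap: AreaMap, p: int, s: int, ms: int
) -> ApicalEstimate:
    """Phase-scaled apical area estimate for jump cell ``(p, s)``.

    Uses the nearest non-jump phase ``q`` at slice ``s`` (cyclic distance,
    earlier phase on ties) and scales its area by the ratio of the summed
    reliable areas over slices ``ms .. s-1`` at phases ``p`` and ``q``::

        A'(p, s) = A(q, s) * sum_i A(p, i) / sum_i A(q, i)
    """
    n_phases = amap.n_phases
    q = None
    for d in range(n_phases // 2 + 1):
        for cand in ((p - d) % n_phases, (p + d) % n_phases):
            if not amap.jump[cand, s]:
                q = cand
                break
        if q is not None:
            break
    if q is None:
        raise NoReliablePhaseError(f"no non-jump phase at slice {s}")
    num = float(amap.area[p, ms:s].sum())
    den = float(amap.area[q, ms:s].sum())
    if den == 0:
        raise ZeroDivisionError(
            f"phase-scaled estimate undefined: reference section empty at phase {q}"
        )
    return ApicalEstimate(
        area_est=float(amap.area[q, s]) * num / den,
        method="phase-scaled",
        source_phase=int(q),
    )


def estimate_apical_cone(a1: float, a2: float) -> float:
    """Cone extrapolation of an apical area from the two slices before it.

    Assuming the equivalent circular radius tapers linearly (a cone's
    cross-sections), ``r' = 2*sqrt(a1) - sqrt(a2)`` up to a common factor,
    hence ``A' = (2*sqrt(a1) - sqrt(a2))**2``, clamped to zero once the
    radius extrapolates past the apex.  ``a1`` is the area one slice closer
    to the target, ``a2`` two slices closer.
    """
    if a1 < 0 or a2 < 0:
        raise ValueError("areas must be non-negative")
    r = 2.0 * math.sqrt(a1) - math.sqrt(a2)
    return r * r if r > 0 else 0.0


# --------------------------------------------------------------------------
# basal detection


def smooth_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological closing then opening with a radius-3 disk."""
    mask = np.asarray(mask, dtype=bool)
    return opening(closing(mask, _DISK3), _DISK3).astype(bool)


def build_polar_map(mask: np.ndarray, center: tuple[float, float]) -> PolarMap:
    """Polar profile of a binary mask around ``center``.

    Rays are marched outward in 0.5 px steps for each of 360 one-degree
    bins; samples outside the image count as background.  Raises when the
    centre pixel is not inside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    cr, cc = float(center[0]), float(center[1])
    ir, ic = int(round(cr)), int(round(cc))
    if not (0 <= ir < h and 0 <= ic < w) or not mask[ir, ic]:
        raise ValueError(f"polar-map center ({cr:.1f}, {cc:.1f}) outside mask")

    max_r = math.hypot(max(cr, h - 1 - cr), max(cc, w - 1 - cc))
    radii = np.arange(0.0, max_r + RADIAL_STEP_PX, RADIAL_STEP_PX)
    ang = np.deg2rad(np.arange(N_ANGULAR_BINS, dtype=float))
    dr = np.sin(ang)[:, None]  # angle 0 along +col, increasing toward +row
    dc = np.cos(ang)[:, None]
    rr = np.rint(cr + radii[None, :] * dr).astype(int)
    cc_idx = np.rint(cc + radii[None, :] * dc).astype(int)
    inside = (rr >= 0) & (rr < h) & (cc_idx >= 0) & (cc_idx < w)
    samples = np.zeros(rr.shape, dtype=bool)
    samples[inside] = mask[rr[inside], cc_idx[inside]]

    # first start index of a background run spanning >= MIN_ZERO_RUN_PX:
    # window of L consecutive background samples covers (L-1)*step pixels
    length = int(round(MIN_ZERO_RUN_PX / RADIAL_STEP_PX)) + 1
    bg = (~samples).astype(np.int64)
    csum = np.cumsum(bg, axis=1)
    pad = np.zeros((N_ANGULAR_BINS, 1), dtype=np.int64)
    csum = np.concatenate([pad, csum], axis=1)
    wsum = csum[:, length:] - csum[:, :-length]  # (360, n_r - L + 1)
    full = wsum == length
    has_run = full.any(axis=1)
    first = np.argmax(full, axis=1)

    # fallback for rays that exit the image before a clear background run
    any_out = ~inside.all(axis=1)
    first_out = np.where(any_out, np.argmin(inside, axis=1), len(radii) - 1)
    idx = np.where(has_run, first, first_out)
    radius0 = radii[idx]

    myo_points = np.zeros((N_ANGULAR_BINS, 2, 2), dtype=int)
    sin_a = np.sin(np.deg2rad(np.arange(N_ANGULAR_BINS)))
    cos_a = np.cos(np.deg2rad(np.arange(N_ANGULAR_BINS)))
    for j, extra in enumerate((1.0, 2.0)):
        pr = np.rint(cr + (radius0 + extra) * sin_a).astype(int)
        pc = np.rint(cc + (radius0 + extra) * cos_a).astype(int)
        myo_points[:, j, 0] = np.clip(pr, 0, h - 1)
        myo_points[:, j, 1] = np.clip(pc, 0, w - 1)
    return PolarMap(radius_of_first_zero=radius0, myo_points=myo_points, center=(cr, cc))


def _circular_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs, treating the array as circular."""
    n = len(flags)
    if flags.all():
        return [(0, n)]
    if not flags.any():
        return []
    doubled = np.concatenate([flags, flags])
    runs = []
    i = 0
    while i < n:
        if doubled[i] and not doubled[i - 1 if i else n - 1]:
            j = i
            while j < 2 * n and doubled[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def find_termination_points(
    polar_jump: PolarMap, polar_ref: PolarMap, d_max: float
) -> Optional[Termination]:
    """Locate the two myocardial termination angles of a basal candidate.

    The zero angle is the middle of the longest contiguous angular run where
    the jump slice's apparent myocardial radius agrees with the reference
    slice's to within ``d_max`` pixels.  Scanning both ways from the zero
    angle, the termination angles are the first bins where the jump radius
    exceeds the reference by more than ``d_max``.  Returns ``None`` when the
    border never recedes (fully enclosed slice — not the base) or when there
    is no agreement region at all (the candidate is likely not LV).
    """
    diff = polar_jump.radius_of_first_zero - polar_ref.radius_of_first_zero
    agree = np.abs(diff) < d_max
    exceed = diff > d_max
    runs = _circular_runs(agree)
    if not runs:
        return None
    if not exceed.any():
        return None
    start, length = max(runs, key=lambda r: (r[1], -r[0]))
    zero = (start + (length - 1) / 2.0) % N_ANGULAR_BINS
    z = int(round(zero)) % N_ANGULAR_BINS

    theta_fwd = theta_bwd = None
    for d in range(1, N_ANGULAR_BINS):
        k = (z + d) % N_ANGULAR_BINS
        if exceed[k]:
            theta_fwd = float(k)
            break
    for d in range(1, N_ANGULAR_BINS):
        k = (z - d) % N_ANGULAR_BINS
        if exceed[k]:
            theta_bwd = float(k)
            break
    if theta_fwd is None or theta_bwd is None:
        return None
    t1, t2 = sorted((theta_fwd, theta_bwd))
    return Termination(theta1=t1, theta2=t2, zero_angle=float(zero))


def mean_myocardial_intensity(
    frame: np.ndarray, polar: PolarMap, bins: Optional[np.ndarray] = None
) -> float:
    """Mean image intensity over the apparent myocardial points.

    ``bins`` restricts the average to a subset of angular bins (e.g. the
    covered sector).
    """
    pts = polar.myo_points if bins is None else polar.myo_points[bins]
    pts = pts.reshape(-1, 2)
    return float(np.asarray(frame, dtype=float)[pts[:, 0], pts[:, 1]].mean())


def _covered_bins(termination: Termination) -> np.ndarray:
    """Boolean mask of angular bins on the enclosed (zero-angle) side."""
    t1, t2 = termination.theta1, termination.theta2
    bins = np.arange(N_ANGULAR_BINS)
    in_arc = (bins >= t1) & (bins <= t2)  # arc from t1 to t2 the short way round
    z = termination.zero_angle % N_ANGULAR_BINS
    zero_in_arc = (z >= t1) and (z <= t2)
    return in_arc if zero_in_arc else ~in_arc


def decide_basal(
    jump_mask: np.ndarray,
    ref_mask: np.ndarray,
    stack_frame: np.ndarray,
    termination: Optional[Termination],
    ref_myo_intensity: float,
) -> BasalDecision:
    """Decide whether a basal jump image still contains LV, and close it.

    ``jump_mask`` is the raw Step-1 region of the jump slice, ``ref_mask``
    the region of the last reliable slice, ``stack_frame`` the intensity
    image of the jump slice.  The decision applies the >= 180° circumference
    rule and the 30% intensity rule; when the slice qualifies, the returned
    mask is the Step-1 region clipped by the straight chord joining the two
    termination points.
    """
    jump_mask = np.asarray(jump_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    rr, cc = np.nonzero(ref_mask)
    center = (float(rr.mean()), float(cc.mean()))
    polar_jump = build_polar_map(smooth_mask(jump_mask), center)

    if termination is None:
        covered = np.ones(N_ANGULAR_BINS, dtype=bool)
        coverage = 360.0
    else:
        covered = _covered_bins(termination)
        coverage = float(covered.sum()) * 360.0 / N_ANGULAR_BINS

    mean_int = mean_myocardial_intensity(stack_frame, polar_jump, covered)
    if ref_myo_intensity <= 0:
        ratio = math.inf
    else:
        ratio = abs(mean_int - ref_myo_intensity) / ref_myo_intensity
    contains = coverage >= 180.0 and ratio <= 0.30

    closed = None
    if contains:
        if termination is None:
            closed = jump_mask.copy()
        else:
            closed = _clip_by_chord(jump_mask, polar_jump, termination)
    return BasalDecision(
        contains_lv=contains,
        termination_angles=None
        if termination is None
        else (termination.theta1, termination.theta2),
        myocardial_coverage_deg=coverage,
        intensity_ratio=ratio,
        closed_mask=closed,
    )


def _clip_by_chord(
    mask: np.ndarray, polar: PolarMap, termination: Termination
) -> np.ndarray:
    """Keep the part of ``mask`` on the zero-angle side of the chord."""
    cr, cc = polar.center

    def _point(theta: float) -> tuple[float, float]:
        k = int(round(theta)) % N_ANGULAR_BINS
        r = polar.radius_of_first_zero[k]
        a = math.radians(theta)
        return (cr + r * math.sin(a), cc + r * math.cos(a))

    p1 = _point(termination.theta1)
    p2 = _point(termination.theta2)
    nz = math.radians(termination.zero_angle)
    # reference point safely on the enclosed side
    k0 = int(round(termination.zero_angle)) % N_ANGULAR_BINS
    ref_r = 0.5 * polar.radius_of_first_zero[k0]
    ref_pt = (cr + ref_r * math.sin(nz), cc + ref_r * math.cos(nz))

    # line through p1-p2: signed side of (row, col) points
    drow, dcol = p2[0] - p1[0], p2[1] - p1[1]
    if drow == 0 and dcol == 0:
        return mask.copy()

    def side(r, c):
        return drow * (c - p1[1]) - dcol * (r - p1[0])

    want = side(*ref_pt)
    rows, cols = np.indices(mask.shape)
    sides = drow * (cols - p1[1]) - dcol * (rows - p1[0])
    if want >= 0:
        keep = sides >= 0
    else:
        keep = sides <= 0
    return mask & keep
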