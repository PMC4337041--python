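"""End-to-end orchestration: Step 1, jump classification, extremity repair,
volumetry.

The pipeline segments every frame from the mid-ventricular anchor outward,
classifies jump images from the area/centroid surface, repairs the apical
extreme by phase-scaled or cone estimation, interrogates the basal jump
slice with the polar-map procedure (closing it with the termination chord
when it still contains LV) and finally reduces the corrected area table to
clinical metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .apex_base import (
    BasalDecision,
    NoReliablePhaseError,
    decide_basal,
    build_polar_map,
    estimate_apical_cone,
    estimate_apical_phase_scaled,
    find_termination_points,
    mean_myocardial_intensity,
    smooth_mask,
)
from .continuity import AreaMap, JumpParams, SegResult, classify_jumps, run_step1
from .geometry import CineStack
from .quantify import LVMetrics, phase_volume, summarize
from .region_grow import GrowConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    grow: GrowConfig = field(default_factory=GrowConfig)
    jumps: JumpParams = field(default_factory=JumpParams)
    #: phases differenced for the initial Hough localization (nominal ED, ES)
    seed_phases: tuple[int, int] = (0, 7)
    #: Hough radius range in pixels; None = scaled from the pixel spacing
    radius_range: Optional[tuple[int, int]] = None
    #: fraction of non-jump phases a slice needs before the slice beyond it
    #: is extended by cone interpolation
    apical_nonjump_fraction: float = 0.9


@dataclass
class PipelineResult:
    seg: SegResult
    amap: AreaMap  # with jump flags, as classified
    final_area: np.ndarray  # (phase, slice) areas after repair, pixels
    metrics: LVMetrics
    basal_decisions: dict  # phase -> BasalDecision for interrogated phases
    apical_methods: dict  # (phase, slice) -> estimation method used


def _repair_apex(
    amap: AreaMap, final_area: np.ndarray, ms: int, cfg: PipelineConfig
) -> tuple[int, dict]:
    """Apply apical estimates; return the apical slice limit and methods."""
    n_phases, n_slices = final_area.shape
    methods: dict = {}
    flagged = amap.first_apical_jump_slice
    if (flagged == -1).all():
        return n_slices - 1, methods
    s_star = int(flagged[flagged >= 0].min())

    jump_phases = [p for p in range(n_phases) if amap.jump[p, s_star]]
    for p in jump_phases:
        try:
            est = estimate_apical_phase_scaled(amap, p, s_star, ms)
            final_area[p, s_star] = est.area_est
            methods[(p, s_star)] = est.method
        except (NoReliablePhaseError, ZeroDivisionError):
            if s_star >= 2:
                final_area[p, s_star] = estimate_apical_cone(
                    final_area[p, s_star - 1], final_area[p, s_star - 2]
                )
                methods[(p, s_star)] = "cone"
            else:
                final_area[p, s_star] = 0.0

    nonjump_fraction = 1.0 - len(jump_phases) / n_phases
    if nonjump_fraction >= cfg.apical_nonjump_fraction and s_star + 1 < n_slices:
        for p in range(n_phases):
            final_area[p, s_star + 1] = estimate_apical_cone(
                final_area[p, s_star], final_area[p, s_star - 1]
            )
            methods[(p, s_star + 1)] = "cone"
        limit = s_star + 1
    else:
        limit = s_star
    if limit + 1 < n_slices:
        final_area[:, limit + 1 :] = 0.0
    return limit, methods


def _repair_base(
    stack: CineStack,
    seg: SegResult,
    amap: AreaMap,
    final_area: np.ndarray,
    params: JumpParams,
) -> tuple[np.ndarray, dict]:
    """Interrogate basal jump slices per phase; return basal indices."""
    n_phases = final_area.shape[0]
    basal = np.zeros(n_phases, dtype=int)
    decisions: dict = {}
    for p in range(n_phases):
        b = int(amap.first_basal_jump_slice[p])
        if b < 0:
            basal[p] = 0
            continue
        ref_s = b + 1
        jump_mask = seg.masks[b, p]
        ref_mask = seg.masks[ref_s, p]
        decision = _interrogate_basal(
            jump_mask, ref_mask, stack.frame(b, p), stack.frame(ref_s, p), params
        )
        decisions[p] = decision
        if decision is not None and decision.contains_lv:
            basal[p] = b
            final_area[p, b] = float(decision.closed_mask.sum())
            if b > 0:
                final_area[p, :b] = 0.0
        else:
            basal[p] = ref_s
            final_area[p, : ref_s] = 0.0
    return basal, decisions


def _interrogate_basal(
    jump_mask, ref_mask, jump_frame, ref_frame, params: JumpParams
) -> Optional[BasalDecision]:
    """Polar-map interrogation of one basal candidate; None when it cannot
    even be mapped (empty masks, centre outside candidate)."""
    if not ref_mask.any() or not jump_mask.any():
        return None
    try:
        rr, cc = np.nonzero(ref_mask)
        center = (float(rr.mean()), float(cc.mean()))
        smooth_ref = smooth_mask(ref_mask)
        smooth_jump = smooth_mask(jump_mask)
        polar_ref = build_polar_map(smooth_ref, center)
        polar_jump = build_polar_map(smooth_jump, center)
    except ValueError:
        return None
    termination = find_termination_points(polar_jump, polar_ref, params.d_max)
    ref_myo = mean_myocardial_intensity(ref_frame, polar_ref)
    return decide_basal(jump_mask, ref_mask, jump_frame, termination, ref_myo)


def run_pipeline(
    stack: CineStack, config: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Run the full automated segmentation and quantification pipeline."""
    cfg = config or PipelineConfig()
    n_phases = stack.n_phases
    pa, pb = cfg.seed_phases
    if pb >= n_phases:
        pb = max(1, n_phases // 3)  # nominal end systole for short cine loops
    seg, amap = run_step1(
        stack, cfg.grow, seed_phases=(pa, pb), radius_range=cfg.radius_range
    )
    ms = stack.middle_slice
    amap = classify_jumps(amap, cfg.jumps, ms)

    final_area = amap.area.copy()
    apical_limit, apical_methods = _repair_apex(amap, final_area, ms, cfg)
    basal, basal_decisions = _repair_base(stack, seg, amap, final_area, cfg.jumps)

    apical = np.empty(n_phases, dtype=int)
    for p in range(n_phases):
        positive = np.nonzero(final_area[p, : apical_limit + 1] > 0)[0]
        apical[p] = int(positive.max()) if positive.size else apical_limit

    volumes = [
        phase_volume(final_area, p, stack.geometry, int(basal[p]), int(apical[p]))
        for p in range(n_phases)
    ]
    metrics = summarize(volumes, apical_slice=apical, basal_slice=basal)
    return PipelineResult(
        seg=seg,
        amap=amap,
        final_area=final_area,
        metrics=metrics,
        basal_decisions=basal_decisions,
        apical_methods=apical_methods,
    )
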