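"""Clinical volumetry: per-phase volumes, EDV/ESV/EF and the filling curve.

Volumes use disk summation (Simpson's rule for a stack of short-axis
slices): each slice contributes its cavity area times the slice spacing
(thickness + gap).  End diastole and end systole are detected from the
measured volume curve as its maximum and minimum, not assumed at fixed
phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .geometry import VoxelGeometry

__all__ = ["LVMetrics", "phase_volume", "summarize", "compare_paired"]


@dataclass
class LVMetrics:
    """LV functional metrics over the cardiac cycle."""

    volume_ml: np.ndarray  # per phase
    edv_ml: float
    esv_ml: float
    ef_pct: float
    ed_phase: int
    es_phase: int
    apical_slice: np.ndarray = field(default=None)  # per phase, -1 unknown
    basal_slice: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        n = len(self.volume_ml)
        if self.apical_slice is None:
            self.apical_slice = np.full(n, -1, dtype=int)
        if self.basal_slice is None:
            self.basal_slice = np.full(n, -1, dtype=int)

    @property
    def n_phases(self) -> int:
        return len(self.volume_ml)


def phase_volume(
    amap_area: np.ndarray,
    p: int,
    geometry: VoxelGeometry,
    basal_slice: int = 0,
    apical_slice: Optional[int] = None,
) -> float:
    """Disk-summation volume (mL) of phase ``p``.

    ``amap_area`` is the final (phase, slice) area table in pixels, with any
    apical estimates and basal closures already applied; slices from
    ``basal_slice`` to ``apical_slice`` inclusive are summed.
    """
    area = np.asarray(amap_area, dtype=float)
    n_slices = area.shape[1]
    if apical_slice is None:
        apical_slice = n_slices - 1
    if basal_slice > apical_slice:
        raise ValueError(
            f"no valid slices at phase {p}: basal {basal_slice} > apical {apical_slice}"
        )
    px_area = geometry.pixel_area_mm2
    total = float(area[p, basal_slice : apical_slice + 1].sum())
    return total * px_area * geometry.slice_spacing / 1000.0


def summarize(
    volumes: Sequence[float],
    apical_slice: Optional[np.ndarray] = None,
    basal_slice: Optional[np.ndarray] = None,
) -> LVMetrics:
    """EDV, ESV and EF from the per-phase volume curve.

    End diastole is the phase of maximal volume, end systole of minimal
    volume (earliest phase on ties).  Raises when EDV is zero — the
    segmentation produced no cavity anywhere.
    """
    v = np.asarray(volumes, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 phases")
    ed = int(np.argmax(v))
    es = int(np.argmin(v))
    edv = float(v[ed])
    esv = float(v[es])
    if edv == 0:
        raise RuntimeError("segmentation failed: EDV is zero")
    return LVMetrics(
        volume_ml=v,
        edv_ml=edv,
        esv_ml=esv,
        ef_pct=100.0 * (edv - esv) / edv,
        ed_phase=ed,
        es_phase=es,
        apical_slice=apical_slice,
        basal_slice=basal_slice,
    )


def compare_paired(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float, float]:
    """Mean, SD and paired-t p-value of the per-case differences ``a - b``.

    Utility for validating automated metrics against manual tracings on a
    user's own cohort.  The SD is the sample standard deviation (ddof=1);
    the p-value is two-sided and NaN when the differences have zero
    variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = float(diff.std(ddof=1))
    if sd == 0:
        p = float("nan")
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return float(diff.mean()), sd, p
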