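"""Synthetic short-axis cine phantom with analytic ground truth.

The left ventricle is modelled as a truncated half-ellipsoid of revolution:
at phase ``p`` the cavity radius at long-axis depth ``z`` is

    r(z, p) = R(p) * sqrt(1 - (z / L)**2),

where ``L`` spans the acquired slices and ``R(p)`` follows a smooth
contraction curve.  Because the cavity contracts radially with
``R(p) = R_ED * sqrt(1 - EF * c(p))`` the analytic volume is exactly
``EDV * (1 - EF * c(p))``, so the end-systolic volume and ejection fraction
hit their targets by construction (up to voxelisation).

A myocardial shell of fixed thickness surrounds the cavity.  On the most
basal slice(s) an angular sector of the shell is replaced by blood-intensity
tissue — an outflow-tract opening — optionally connected to a bright
circular distractor blob emulating the aortic root / atrium.  These are the
structures that make automatic basal detection hard in real data and they
are what the continuity and polar-map stages are tested against.

Ground-truth masks are the noise-free cavity masks; truth volumes are disk
summations over those masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import CineStack, VoxelGeometry

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "contraction_curve",
    "area_map_from_truth",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cine study.

    Defaults reproduce a typical clinical short-axis SSFP acquisition:
    10 slices x 20 phases on a 256x256 matrix with 1.4 mm in-plane spacing
    and 10 mm slice spacing (thickness + gap), EDV 150 mL and EF 0.60 —
    population-typical values — with blood/myocardium/background at
    100/40/10 a.u. and Gaussian noise sigma of 5% of blood intensity.
    """

    n_slices: int = 10
    n_phases: int = 20
    matrix: int = 256
    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry(1.4, 1.4, 10.0)
    )
    edv_target: float = 150.0  # mL
    ef_target: float = 0.60  # fraction of EDV ejected
    blood_intensity: float = 100.0
    myo_intensity: float = 40.0
    background_intensity: float = 10.0
    noise_sigma: float = 5.0
    wall_thickness_mm: float = 8.0
    basal_open_slices: int = 1
    basal_open_angle_deg: float = 150.0
    #: radial length of the blood-intensity outflow channel beyond the shell
    channel_length_mm: float = 20.0
    distractor: bool = True
    distractor_radius_mm: float = 18.0
    #: multiply the distractor intensity by this fraction of blood intensity
    distractor_intensity_factor: float = 1.0
    misregistration_px: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.blood_intensity > self.myo_intensity > self.background_intensity
        ):
            raise ValueError("require blood_intensity > myo_intensity > background")
        if not 0.0 < self.ef_target < 1.0:
            raise ValueError("ef_target must lie in (0, 1)")
        if self.basal_open_slices >= self.n_slices:
            raise ValueError("basal_open_slices must be < n_slices")
        if self.edv_target <= 0:
            raise ValueError("edv_target must be positive")


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom."""

    masks: np.ndarray  # bool, (slice, phase, row, col) — noise-free cavity
    volume_per_phase: np.ndarray  # mL, per phase
    edv: float  # mL
    esv: float  # mL
    ef: float  # percent
    true_apical_slice: np.ndarray  # per phase
    true_basal_slice: np.ndarray  # per phase
    ed_phase: int = 0
    es_phase: int = 0


def contraction_curve(n_phases: int) -> np.ndarray:
    """Normalised contraction fraction ``c(p)`` in [0, 1] per phase.

    Raised-cosine systole over phases ``0 .. ceil(n/3)`` (so nominal end
    systole falls near the conventional eighth reconstructed phase of a
    20-phase study), then a two-segment return: rapid early filling (raised
    cosine down to a diastasis level) followed by slow linear emptying of the
    remainder so that the curve wraps smoothly to ``c(0) = 0``.
    """
    p_es = math.ceil(n_phases / 3)
    c = np.zeros(n_phases, dtype=float)
    p = np.arange(n_phases)
    systole = p <= p_es
    c[systole] = 0.5 * (1.0 - np.cos(np.pi * p[systole] / p_es))
    c_dia = 0.12  # residual contraction during diastasis
    p_fill = p_es + max(2, round(0.35 * (n_phases - p_es)))
    p_fill = min(p_fill, n_phases - 1)
    filling = (p > p_es) & (p <= p_fill)
    frac = (p[filling] - p_es) / (p_fill - p_es)
    c[filling] = c_dia + (1.0 - c_dia) * 0.5 * (1.0 + np.cos(np.pi * frac))
    late = p > p_fill
    # linear decay reaching 0 at the cyclic wrap p == n_phases
    c[late] = c_dia * (n_phases - p[late]) / (n_phases - p_fill)
    return c


def _radius_profile(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-(phase, slice) cavity radii in mm plus slice depths and R_ED."""
    dz = spec.geometry.slice_spacing
    length = spec.n_slices * dz  # long-axis extent covered by the slices
    # analytic half-ellipsoid volume from z=0..L is (2/3)*pi*R^2*L
    r_ed = math.sqrt(3.0 * spec.edv_target * 1000.0 / (2.0 * math.pi * length))
    z = (np.arange(spec.n_slices) + 0.5) * dz
    taper = np.sqrt(np.clip(1.0 - (z / length) ** 2, 0.0, None))
    c = contraction_curve(spec.n_phases)
    scale = np.sqrt(1.0 - spec.ef_target * c)  # radius scale per phase
    radii = r_ed * scale[:, None] * taper[None, :]  # (phase, slice), mm
    return radii, z, r_ed


def generate_phantom(spec: PhantomSpec) -> tuple[CineStack, PhantomTruth]:
    """Generate a noisy cine stack and its noise-free ground truth.

    Deterministic given ``spec.rng_seed``.  Raises if the end-diastolic
    cavity (plus shell and any distractor) would not fit the field of view.
    """
    radii_mm, _z, r_ed = _radius_profile(spec)
    geom = spec.geometry
    n = spec.matrix
    sp_r, sp_c = geom.pixel_spacing_row, geom.pixel_spacing_col
    center = ((n - 1) / 2.0, (n - 1) / 2.0)

    shell_out_ed = r_ed + spec.wall_thickness_mm
    channel_outer = shell_out_ed + spec.channel_length_mm
    reach = channel_outer
    if spec.distractor and spec.basal_open_slices > 0:
        # distractor overlaps the channel end by 4 mm so they stay connected
        dist_center_mm = channel_outer + spec.distractor_radius_mm - 4.0
        reach = dist_center_mm + spec.distractor_radius_mm
    half_fov = (n / 2.0 - 2.0) * min(sp_r, sp_c)
    if reach > half_fov:
        raise ValueError(
            f"edv_target {spec.edv_target} mL infeasible: phantom structures "
            f"reach {reach:.1f} mm but the half field of view is {half_fov:.1f} mm"
        )

    rng = np.random.default_rng(spec.rng_seed)
    shifts = np.zeros((spec.n_slices, 2))
    if spec.misregistration_px > 0:
        shifts = rng.uniform(
            -spec.misregistration_px, spec.misregistration_px, size=(spec.n_slices, 2)
        )

    rows = np.arange(n, dtype=float)
    cols = np.arange(n, dtype=float)
    open_half = math.radians(spec.basal_open_angle_deg) / 2.0
    bisector = 0.0  # opening points along +col from the LV centre

    images = np.empty((spec.n_slices, spec.n_phases, n, n), dtype=float)
    masks = np.zeros((spec.n_slices, spec.n_phases, n, n), dtype=bool)

    for s in range(spec.n_slices):
        cr = center[0] + shifts[s, 0]
        cc = center[1] + shifts[s, 1]
        dr = (rows[:, None] - cr) * sp_r
        dc = (cols[None, :] - cc) * sp_c
        dist = np.hypot(dr, dc)
        ang = np.arctan2(dr, dc)  # 0 along +col
        in_sector = np.abs(np.angle(np.exp(1j * (ang - bisector)))) <= open_half
        is_open = s < spec.basal_open_slices
        if is_open and spec.distractor:
            d_cr = cr + dist_center_mm * math.sin(bisector) / sp_r
            d_cc = cc + dist_center_mm * math.cos(bisector) / sp_c
            d_dist = np.hypot(
                (rows[:, None] - d_cr) * sp_r, (cols[None, :] - d_cc) * sp_c
            )
        for p in range(spec.n_phases):
            r_cav = radii_mm[p, s]
            cavity = dist <= r_cav
            img = np.full((n, n), spec.background_intensity)
            if r_cav > 0:
                shell = (dist <= r_cav + spec.wall_thickness_mm) & ~cavity
                if is_open and spec.basal_open_angle_deg > 0:
                    channel = in_sector & ~cavity & (dist <= channel_outer)
                    img[shell & ~channel] = spec.myo_intensity
                    img[channel] = spec.blood_intensity
                else:
                    img[shell] = spec.myo_intensity
                img[cavity] = spec.blood_intensity
            if is_open and spec.distractor:
                img[d_dist <= spec.distractor_radius_mm] = (
                    spec.blood_intensity * spec.distractor_intensity_factor
                )
            images[s, p] = img
            masks[s, p] = cavity

    if spec.noise_sigma > 0:
        images += rng.normal(0.0, spec.noise_sigma, size=images.shape)
        np.clip(images, 0.0, None, out=images)

    counts = masks.sum(axis=(2, 3))  # (slice, phase)
    vol = counts.sum(axis=0) * geom.pixel_area_mm2 * geom.slice_spacing / 1000.0
    nonzero = counts > 0
    apical = np.array(
        [
            int(np.max(np.nonzero(nonzero[:, p])[0])) if nonzero[:, p].any() else -1
            for p in range(spec.n_phases)
        ]
    )
    basal = np.array(
        [
            int(np.min(np.nonzero(nonzero[:, p])[0])) if nonzero[:, p].any() else -1
            for p in range(spec.n_phases)
        ]
    )
    edv = float(vol.max())
    esv = float(vol.min())
    truth = PhantomTruth(
        masks=masks,
        volume_per_phase=vol,
        edv=edv,
        esv=esv,
        ef=100.0 * (edv - esv) / edv if edv > 0 else 0.0,
        true_apical_slice=apical,
        true_basal_slice=basal,
        ed_phase=int(np.argmax(vol)),
        es_phase=int(np.argmin(vol)),
    )
    stack = CineStack(intensities=images, geometry=geom)
    return stack, truth


def area_map_from_truth(truth: PhantomTruth, geometry: VoxelGeometry):
    """Build an :class:`~lvfast.continuity.AreaMap` from ground-truth masks.

    Areas are pixel counts and centroids pixel coordinates; no jump flags are
    set.  Used as a clean fixture for the continuity stage.
    """
    from .continuity import AreaMap

    n_slices, n_phases = truth.masks.shape[:2]
    area = np.zeros((n_phases, n_slices))
    c_row = np.full((n_phases, n_slices), np.nan)
    c_col = np.full((n_phases, n_slices), np.nan)
    for s in range(n_slices):
        for p in range(n_phases):
            m = truth.masks[s, p]
            cnt = int(m.sum())
            area[p, s] = cnt
            if cnt:
                rr, cc = np.nonzero(m)
                c_row[p, s] = rr.mean()
                c_col[p, s] = cc.mean()
    return AreaMap(area=area, centroid_row=c_row, centroid_col=c_col)


def scaled_spec(spec: PhantomSpec, matrix: int) -> PhantomSpec:
    """Same physical phantom rasterised on a different matrix size.

    In-plane spacing is rescaled so the field of view is preserved; used for
    voxelisation-convergence checks.
    """
    fov = spec.matrix * spec.geometry.pixel_spacing_row
    sp = fov / matrix
    geom = VoxelGeometry(sp, sp, spec.geometry.slice_spacing)
    return replace(spec, matrix=matrix, geometry=geom)
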