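"""Apical estimation formulas and the polar-map basal procedure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvfast import (
    AreaMap,
    JumpParams,
    build_polar_map,
    decide_basal,
    estimate_apical_cone,
    estimate_apical_phase_scaled,
    find_termination_points,
    smooth_mask,
)
from lvfast.apex_base import (
    NoReliablePhaseError,
    PolarMap,
    Termination,
    mean_myocardial_intensity,
)


def cone_oracle(a1: float, a2: float) -> float:
    """Linear extrapolation of the equivalent circular radius."""
    r1 = math.sqrt(a1 / math.pi)
    r2 = math.sqrt(a2 / math.pi)
    r = 2 * r1 - r2
    return math.pi * r * r if r > 0 else 0.0


def filled_disk(shape, center, radius):
    rows, cols = np.indices(shape)
    return np.hypot(rows - center[0], cols - center[1]) <= radius


def wedge(shape, center, r_in, r_out, theta1, theta2):
    """Annular sector between the two angles (degrees, row-toward from +col)."""
    rows, cols = np.indices(shape)
    d = np.hypot(rows - center[0], cols - center[1])
    ang = np.degrees(np.arctan2(rows - center[0], cols - center[1])) % 360
    t1, t2 = theta1 % 360, theta2 % 360
    if t1 <= t2:
        in_arc = (ang >= t1) & (ang <= t2)
    else:
        in_arc = (ang >= t1) | (ang <= t2)
    return (d >= r_in) & (d <= r_out) & in_arc


class TestConeInterpolation:
    @pytest.mark.parametrize("a", [0.0, 1.0, 25.0, 1000.0])
    def test_cylinder_limit_is_identity(self, a):
        assert estimate_apical_cone(a, a) == pytest.approx(a)

    def test_apex_reached_gives_zero(self):
        assert estimate_apical_cone(25.0, 100.0) == 0.0

    def test_hand_worked_case(self):
        assert estimate_apical_cone(64.0, 100.0) == pytest.approx(36.0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_apical_cone(-1.0, 4.0)

    @given(a1=st.floats(0, 1e4), a2=st.floats(0, 1e4))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_agrees_with_radius_extrapolation_oracle(self, a1, a2):
        assert estimate_apical_cone(a1, a2) == pytest.approx(
            cone_oracle(a1, a2), abs=1e-9, rel=1e-9
        )

    @given(a=st.floats(0, 1e4))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_never_negative(self, a):
        assert estimate_apical_cone(a, 4.1 * a + 1) >= 0.0


def area_map_with_jumps(area, jump):
    area = np.asarray(area, dtype=float)
    amap = AreaMap(
        area=area,
        centroid_row=np.zeros_like(area),
        centroid_col=np.zeros_like(area),
    )
    amap.jump = np.asarray(jump, dtype=bool)
    return amap


class TestPhaseScaledEstimate:
    def test_hand_worked_case(self):
        # A(q,s)=50, sums over ms..s-1: 400 at p, 500 at q -> A' = 40
        area = np.zeros((2, 4))
        area[0, 1:3] = [250, 150]  # phase 0 = p, slices 1..2 sum 400
        area[1, 1:3] = [300, 200]  # phase 1 = q, sum 500
        area[1, 3] = 50.0
        jump = np.zeros((2, 4), dtype=bool)
        jump[0, 3] = True
        est = estimate_apical_phase_scaled(area_map_with_jumps(area, jump), 0, 3, 1)
        assert est.area_est == pytest.approx(40.0)
        assert est.source_phase == 1
        assert est.method == "phase-scaled"

    def test_identity_when_phase_itself_is_reliable(self):
        area = np.abs(np.cos(np.arange(12.0)))[:, None] * np.ones((12, 5)) + 1
        amap = area_map_with_jumps(area, np.zeros((12, 5), bool))
        est = estimate_apical_phase_scaled(amap, 3, 4, 2)
        assert est.area_est == pytest.approx(area[3, 4])
        assert est.source_phase == 3

    def test_no_reliable_phase_raises(self):
        area = np.ones((4, 5))
        jump = np.zeros((4, 5), bool)
        jump[:, 4] = True
        with pytest.raises(NoReliablePhaseError):
            estimate_apical_phase_scaled(area_map_with_jumps(area, jump), 0, 4, 2)

    def test_zero_reference_section_raises(self):
        area = np.zeros((2, 5))
        area[:, 4] = 10.0
        jump = np.zeros((2, 5), bool)
        jump[0, 4] = True
        with pytest.raises(ZeroDivisionError):
            estimate_apical_phase_scaled(area_map_with_jumps(area, jump), 0, 4, 2)

    def test_nearest_reliable_phase_cyclic_with_earlier_tie(self):
        area = np.ones((6, 5)) * 10
        jump = np.zeros((6, 5), bool)
        jump[[0, 1, 5], 4] = True  # phases 2 and 4 equidistant from p=3...
        # for p=0 the nearest non-jump phases are 2 and 4 (distance 2);
        # the earlier (counter-clockwise) one, 4 == (0-2) mod 6, wins
        est = estimate_apical_phase_scaled(area_map_with_jumps(area, jump), 0, 4, 2)
        assert est.source_phase == 4


class TestSmoothMask:
    def test_small_hole_closed(self):
        mask = filled_disk((64, 64), (32, 32), 15)
        holey = mask.copy()
        holey[30:32, 30:32] = False
        out = smooth_mask(holey)
        assert out[30:32, 30:32].all()

    def test_isolated_speck_removed(self):
        mask = filled_disk((64, 64), (32, 32), 15)
        specky = mask.copy()
        specky[5, 5] = specky[5, 6] = True
        out = smooth_mask(specky)
        assert not out[5, 5] and not out[5, 6]

    def test_large_convex_mask_nearly_unchanged(self):
        mask = filled_disk((64, 64), (32, 32), 18)
        out = smooth_mask(mask)
        assert (out ^ mask).sum() <= 0.05 * mask.sum()


class TestPolarMap:
    def test_filled_circle_radii(self):
        mask = filled_disk((96, 96), (48, 48), 20)
        polar = build_polar_map(mask, (48, 48))
        assert (polar.radius_of_first_zero >= 19).all()
        assert (polar.radius_of_first_zero <= 21).all()

    def test_open_sector_radii_exceed_closed_sector(self):
        center = (48, 48)
        mask = filled_disk((96, 96), center, 14) | wedge(
            (96, 96), center, 0, 40, 30, 120
        )
        polar = build_polar_map(mask, center)
        open_bins = polar.radius_of_first_zero[35:115]
        closed_bins = polar.radius_of_first_zero[130:360]
        assert open_bins.min() > closed_bins.max() + 10

    def test_single_pixel_mask(self):
        mask = np.zeros((32, 32), bool)
        mask[16, 16] = True
        polar = build_polar_map(mask, (16, 16))
        assert (polar.radius_of_first_zero <= 1.0).all()

    def test_center_outside_mask_raises(self):
        mask = filled_disk((64, 64), (20, 20), 8)
        with pytest.raises(ValueError, match="outside mask"):
            build_polar_map(mask, (50, 50))

    def test_myocardial_points_lie_just_beyond_border(self):
        mask = filled_disk((96, 96), (48, 48), 20)
        polar = build_polar_map(mask, (48, 48))
        d = np.hypot(
            polar.myo_points[:, :, 0] - 48.0, polar.myo_points[:, :, 1] - 48.0
        )
        assert (d >= polar.radius_of_first_zero[:, None] - 0.8).all()
        assert (d <= polar.radius_of_first_zero[:, None] + 2.8).all()


def synthetic_polar(radii) -> PolarMap:
    radii = np.asarray(radii, dtype=float)
    pts = np.zeros((360, 2, 2), dtype=int)
    return PolarMap(radius_of_first_zero=radii, myo_points=pts, center=(0.0, 0.0))


class TestTerminationPoints:
    def test_open_arc_located_within_one_bin(self):
        r_ref = np.full(360, 20.0)
        r_jump = r_ref.copy()
        r_jump[30:141] = 35.0
        term = find_termination_points(
            synthetic_polar(r_jump), synthetic_polar(r_ref), d_max=6.0
        )
        assert term is not None
        assert term.theta1 == pytest.approx(30, abs=1)
        assert term.theta2 == pytest.approx(140, abs=1)
        # zero angle in the middle of the agreeing arc (141..389 ~ 265)
        assert term.zero_angle == pytest.approx(265, abs=1)

    def test_fully_enclosed_returns_none(self):
        r = np.full(360, 18.0)
        assert find_termination_points(
            synthetic_polar(r), synthetic_polar(r), 6.0
        ) is None

    def test_zero_angle_taken_in_longest_agreement_run(self):
        r_ref = np.full(360, 20.0)
        r_jump = np.full(360, 40.0)
        r_jump[0:170] = 20.0  # 170° agreement run
        r_jump[220:280] = 20.0  # 60° agreement run
        term = find_termination_points(
            synthetic_polar(r_jump), synthetic_polar(r_ref), 6.0
        )
        assert term is not None
        assert 0 <= term.zero_angle <= 170


class TestDecideBasal:
    shape = (128, 128)
    center = (64, 64)

    def _frame(self, myo_value=40.0):
        """Intensity image: bright cavity, myocardial ring at `myo_value`."""
        img = np.full(self.shape, 10.0)
        rows, cols = np.indices(self.shape)
        d = np.hypot(rows - 64, cols - 64)
        img[(d > 20) & (d <= 28)] = myo_value
        img[d <= 20] = 100.0
        return img

    def _masks(self, open_deg):
        ref = filled_disk(self.shape, self.center, 20)
        half = open_deg / 2
        jump = ref | wedge(self.shape, self.center, 0, 45, -half, half)
        return jump, ref

    def _decision(self, open_deg, myo_value=40.0):
        jump, ref = self._masks(open_deg)
        frame = self._frame(myo_value)
        # leak is blood-bright inside the wedge
        frame[jump & ~filled_disk(self.shape, self.center, 20)] = 100.0
        polar_ref = build_polar_map(smooth_mask(ref), self.center)
        polar_jump = build_polar_map(smooth_mask(jump), self.center)
        term = find_termination_points(polar_jump, polar_ref, JumpParams().d_max)
        ref_myo = mean_myocardial_intensity(self._frame(40.0), polar_ref)
        return decide_basal(jump, ref, frame, term, ref_myo)

    def test_150deg_opening_with_myocardial_points_is_lv(self):
        d = self._decision(150)
        assert d.contains_lv
        assert d.myocardial_coverage_deg == pytest.approx(210, abs=8)
        assert d.closed_mask is not None
        # the chord closure restores most of the true cavity disk
        truth = filled_disk(self.shape, self.center, 20)
        assert d.closed_mask.sum() >= 0.60 * truth.sum()
        assert d.closed_mask.sum() <= 1.10 * truth.sum()

    def test_200deg_opening_fails_circumference_rule(self):
        d = self._decision(200)
        assert not d.contains_lv
        assert d.myocardial_coverage_deg < 180

    def test_blood_bright_myocardial_points_fail_intensity_rule(self):
        d = self._decision(150, myo_value=100.0)
        assert d.intensity_ratio > 0.30
        assert not d.contains_lv

    def test_monotone_in_coverage(self):
        # widening the myocardial coverage never flips LV -> not LV
        decisions = [self._decision(deg) for deg in (200, 170, 150, 120)]
        states = [d.contains_lv for d in decisions]
        assert states == sorted(states)  # False before True, never back

    def test_termination_none_keeps_mask_when_intensity_matches(self):
        ref = filled_disk(self.shape, self.center, 20)
        d = decide_basal(ref, ref, self._frame(), None, 40.0)
        assert d.contains_lv
        assert d.myocardial_coverage_deg == 360.0
        np.testing.assert_array_equal(d.closed_mask, ref)
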