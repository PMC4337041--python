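"""Jump classification and the Step-1 sweep over the whole stack."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvfast import (
    AreaMap,
    JumpParams,
    VoxelGeometry,
    center_displacement,
    classify_jumps,
    generate_phantom,
    jump_ratio,
    run_step1,
)

from conftest import small_spec


def smooth_area_map(n_phases=12, n_slices=8, base=100.0) -> AreaMap:
    """A gently varying map: adjacent ratios <= 1.3, displacements <= 2 px."""
    p = np.arange(n_phases)[:, None]
    s = np.arange(n_slices)[None, :]
    area = base * (1 + 0.2 * np.cos(2 * np.pi * p / n_phases)) * (1 - 0.08 * s)
    c_row = 64 + 0.5 * np.cos(2 * np.pi * p / n_phases) + 0.0 * s
    c_col = np.full((n_phases, n_slices), 64.0) + 0.3 * s
    return AreaMap(area=area, centroid_row=c_row, centroid_col=c_col)


def brute_force_spatial_flags(amap: AreaMap, params: JumpParams, ms: int):
    """Independent re-statement of the outward sweep: per phase, first
    violating slice on each side and everything beyond it."""
    flags = np.zeros_like(amap.area, dtype=bool)
    for p in range(amap.n_phases):
        for direction in (1, -1):
            s = ms + direction
            while 0 <= s < amap.n_slices:
                ref = s - direction
                j = (
                    math.inf
                    if amap.area[p, ref] == 0
                    else amap.area[p, s] / amap.area[p, ref]
                )
                d = math.hypot(
                    amap.centroid_row[p, s] - amap.centroid_row[p, ref],
                    amap.centroid_col[p, s] - amap.centroid_col[p, ref],
                )
                if j > params.j_max or d > params.d_max:
                    if direction > 0:
                        flags[p, s:] = True
                    else:
                        flags[p, : s + 1] = True
                    break
                s += direction
    return flags


class TestJumpPrimitives:
    @pytest.mark.parametrize(
        "a_test,a_ref,expected",
        [(300, 100, 3.0), (100, 100, 1.0), (50, 0, math.inf)],
    )
    def test_jump_ratio(self, a_test, a_ref, expected):
        assert jump_ratio(a_test, a_ref) == expected

    @pytest.mark.parametrize(
        "c_test,c_ref,expected",
        [
            ((10, 10), (13, 14), 5.0),
            ((7.5, 3.5), (7.5, 3.5), 0.0),
            ((10, 10), (math.nan, math.nan), math.inf),
        ],
    )
    def test_center_displacement(self, c_test, c_ref, expected):
        assert center_displacement(c_test, c_ref) == expected

    def test_params_validation(self):
        with pytest.raises(ValueError):
            JumpParams(j_max=1.0)
        with pytest.raises(ValueError):
            JumpParams(d_max=0.0)


class TestClassifyJumps:
    def test_area_blowup_at_apical_slice_flagged_everywhere(self):
        amap = smooth_area_map()
        amap.area[:, 7] = 310.0  # ~3.1x its neighbour — beyond J_max
        out = classify_jumps(amap, JumpParams(), ms=4)
        assert out.jump[:, 7].all()
        assert not out.jump[:, :7].any()
        assert (out.first_apical_jump_slice == 7).all()
        assert (out.first_basal_jump_slice == -1).all()

    def test_smooth_map_has_no_flags(self):
        out = classify_jumps(smooth_area_map(), JumpParams(), ms=4)
        assert not out.jump.any()
        assert (out.first_apical_jump_slice == -1).all()
        assert (out.first_basal_jump_slice == -1).all()

    def test_centroid_shift_flagged_by_displacement_rule(self):
        amap = smooth_area_map()
        amap.centroid_row[:, :2] += 8.0  # basal misregistration, areas smooth
        out = classify_jumps(amap, JumpParams(), ms=4)
        assert out.jump[:, 1].all()  # flagged at the 8-px shift
        assert out.jump[:, 0].all()  # and beyond it toward the base
        assert not out.jump[:, 2:].any()
        assert (out.first_basal_jump_slice == 1).all()

    def test_matches_bruteforce_rule_evaluation(self, rng):
        for _ in range(20):
            amap = smooth_area_map()
            # inject random anomalies at the extreme slices only
            for p in rng.choice(12, size=2, replace=False):
                amap.area[p, 7] *= 3.1
            for p in rng.choice(12, size=2, replace=False):
                amap.centroid_col[p, 0] += 8.0
            params = JumpParams()
            out = classify_jumps(amap, params, ms=4)
            np.testing.assert_array_equal(
                out.jump, brute_force_spatial_flags(amap, params, 4)
            )

    def test_empty_mid_slice_is_hard_error(self):
        amap = smooth_area_map()
        amap.area[3, 4] = 0.0
        with pytest.raises(RuntimeError, match="mid-ventricular"):
            classify_jumps(amap, JumpParams(), ms=4)

    def test_invariant_to_global_centroid_translation(self):
        amap = smooth_area_map()
        amap.area[:, 7] = 310.0
        amap.centroid_row[:, 0] += 7.0
        out1 = classify_jumps(amap, JumpParams(), ms=4)
        shifted = AreaMap(
            area=amap.area.copy(),
            centroid_row=amap.centroid_row + 123.4,
            centroid_col=amap.centroid_col - 55.0,
        )
        out2 = classify_jumps(shifted, JumpParams(), ms=4)
        np.testing.assert_array_equal(out1.jump, out2.jump)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_flag_count_monotone_as_thresholds_tighten(self, seed):
        rng = np.random.default_rng(seed)
        amap = smooth_area_map()
        amap.area *= rng.uniform(0.5, 2.0, size=amap.area.shape)
        amap.centroid_row += rng.normal(0, 3, size=amap.area.shape)
        loose = JumpParams(j_max=3.0, d_max=8.0)
        tight = JumpParams(j_max=2.0, d_max=4.0)
        n_loose = classify_jumps(amap, loose, ms=4).jump.sum()
        n_tight = classify_jumps(amap, tight, ms=4).jump.sum()
        assert n_tight >= n_loose


class TestRunStep1:
    def test_minimal_stack_shape_contract(self):
        spec = small_spec(
            n_slices=5, n_phases=10, matrix=64,
            geometry=VoxelGeometry(5.6, 5.6, 10.0),
            noise_sigma=0.0, basal_open_slices=0, basal_open_angle_deg=0.0,
            distractor=False,
        )
        stack, _truth = generate_phantom(spec)
        seg, amap = run_step1(stack, seed_phases=(0, 4))
        assert amap.area.shape == (10, 5)
        assert seg.masks.shape[:2] == (5, 10)

    def test_noise_free_phantom_interior_dice(self, clean_small_phantom):
        _spec, stack, truth = clean_small_phantom
        seg, _amap = run_step1(stack)
        n_s = stack.n_slices
        for s in range(1, n_s - 1):  # interior slices
            for p in (0, truth.es_phase):
                tm = truth.masks[s, p]
                m = seg.masks[s, p]
                dice = 2 * (m & tm).sum() / max(m.sum() + tm.sum(), 1)
                assert dice >= 0.95, (s, p, dice)

    def test_open_basal_slice_produces_jump_areas(self):
        spec = small_spec()  # 150° opening + blood-bright distractor
        stack, truth = generate_phantom(spec)
        seg, amap = run_step1(stack)
        interior = amap.area[:, 1]
        leaked_area = amap.area[:, 0]
        # the open slice's grown region spills into the outflow channel and
        # distractor: areas well above the adjacent closed slice
        assert np.median(leaked_area / interior) > 2.0
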