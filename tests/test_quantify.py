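"""Uptake metrics: slice stats, whole-valve, MDS, blood pools, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import valvepet as vp
from valvepet.geometry import EnFaceStack, fit_valve_plane
from valvepet.quantify import MDSSelection, QuantifyError, polygon_to_mask
from valvepet.rois import RoiSet


def _stats(means, maxes=None):
    maxes = means if maxes is None else maxes
    return [vp.SliceStats(i, m, x, 10) for i, (m, x) in enumerate(zip(means, maxes))]


def _toy_stack(slices, spacing=1.0, thickness=1.0):
    plane = fit_valve_plane((0, 0, 0), (10, 0, 0), (0, 10, 0))
    arr = np.asarray(slices, dtype=float)
    return EnFaceStack(arr, thickness, spacing, plane,
                       np.zeros(arr.shape[0], dtype=bool))


class TestSliceStats:
    def test_uniform_slice(self):
        s = vp.slice_suv_stats(np.full((4, 4), 2.5), np.ones((4, 4), bool))
        assert (s.suv_mean, s.suv_max) == (2.5, 2.5)

    def test_hand_values(self):
        grid = np.array([[1.0, 2.0], [3.0, 6.0]])
        s = vp.slice_suv_stats(grid, np.ones((2, 2), bool))
        assert (s.suv_mean, s.suv_max) == (3.0, 6.0)

    def test_empty_roi_names_slice(self):
        with pytest.raises(QuantifyError, match="slice 7"):
            vp.slice_suv_stats(np.ones((3, 3)), np.zeros((3, 3), bool), index=7)

    def test_polygon_pixel_center_containment(self):
        u = v = np.arange(5, dtype=float)  # centers 0..4
        square = np.array([[0.5, 0.5], [2.5, 0.5], [2.5, 2.5], [0.5, 2.5]])
        mask = polygon_to_mask(square, u, v)
        assert mask.sum() == 4  # centers (1,1), (1,2), (2,1), (2,2)

    def test_max_at_least_mean_invariant(self, rng):
        for _ in range(20):
            grid = rng.normal(size=(8, 8))
            mask = rng.random((8, 8)) < 0.5
            if not mask.any():
                continue
            s = vp.slice_suv_stats(grid, mask)
            assert s.suv_max >= s.suv_mean


class TestWholeValve:
    def test_means_average(self):
        assert vp.whole_valve_uptake(_stats([1, 2, 3]))[0] == 2.0

    def test_maxes_average(self):
        assert vp.whole_valve_uptake(_stats([1, 1, 1], [2, 2, 8]))[1] == 4.0

    def test_single_slice_passthrough(self):
        assert vp.whole_valve_uptake(_stats([1.3])) == (1.3, 1.3)

    def test_empty_rejected(self):
        with pytest.raises(QuantifyError):
            vp.whole_valve_uptake([])


class TestMDS:
    def test_peaked_profile(self):
        mds = vp.mds_uptake(_stats([1.0, 2.0, 5.0, 4.0, 1.0]))
        assert mds.mean_pair == (2, 3) and mds.mean_value == 4.5

    def test_tie_breaks_to_lower_index(self):
        mds = vp.mds_uptake(_stats([3, 3, 3]))
        assert mds.mean_pair == (0, 1) and mds.mean_value == 3.0

    def test_bimodal_profile_may_fall_below_whole_valve(self):
        stats = _stats([5.0, 0.0, 5.0])
        mds = vp.mds_uptake(stats)
        assert mds.mean_pair == (0, 1) and mds.mean_value == 2.5
        assert vp.whole_valve_uptake(stats)[0] == pytest.approx(10 / 3)

    def test_needs_two_slices(self):
        with pytest.raises(QuantifyError):
            vp.mds_uptake(_stats([1.0]))

    def test_mean_and_max_pairs_selected_independently(self):
        mds = vp.mds_uptake(_stats([1, 5, 5, 1], [9, 5, 5, 9]))
        assert mds.mean_pair == (1, 2)
        assert mds.max_pair == (0, 1)  # tie with (2,3) -> caudal pair

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 12))
            prof = rng.random(n) * 5
            mds = vp.mds_uptake(_stats(prof))
            pairs = [(i, (prof[i] + prof[i + 1]) / 2) for i in range(n - 1)]
            best = max(pairs, key=lambda t: (t[1], -t[0]))
            assert mds.mean_pair == (best[0], best[0] + 1)
            assert mds.mean_value == pytest.approx(best[1])


class TestBloodPool:
    def test_vein_hand_average(self):
        bp = vp.blood_pool_brachiocephalic([1.2, 1.1, 1.0, 0.9, 0.8])
        assert bp.value == pytest.approx(1.0)
        assert bp.slice_values == [1.2, 1.1, 1.0, 0.9, 0.8]

    def test_vein_uniform(self):
        assert vp.blood_pool_brachiocephalic([1.1] * 5).value == pytest.approx(1.1)

    def test_vein_requires_five_slices(self):
        with pytest.raises(QuantifyError):
            vp.blood_pool_brachiocephalic([1.0] * 4)

    def test_atrium_hand_average(self):
        stack = _toy_stack([np.full((9, 9), 1.0), np.full((9, 9), 1.2)])
        mask = np.zeros((9, 9), bool)
        mask[3:6, 3:6] = True
        rois = RoiSet({}, {}, {}, atrium_slice=0, atrium_mask=mask)
        bp = vp.blood_pool_right_atrium(stack, rois)
        assert bp.value == pytest.approx(1.1)
        assert bp.method == "right_atrium"

    def test_atrium_recovers_phantom_blood_within_2pct(self):
        # no noise, mild blur: estimate within 2% of the configured SUV
        cfg = vp.PhantomConfig.ideal(psf_fwhm_mm=4.0, blood_suv=1.3)
        series, truth = vp.generate_phantom(cfg, scan_index=1)
        run = vp.RunConfig(roi_level_jitter_mm=0.0)
        res = vp.analyze_scan(series, truth, run)["right_atrium"]
        assert res.blood_pool.value == pytest.approx(1.3, rel=0.02)


class TestCorrections:
    def test_tbr_hand_values(self):
        assert vp.tbr(2.2, 1.1) == pytest.approx(2.0)
        assert vp.tbr(1.1, 1.1) == pytest.approx(1.0)

    def test_tbr_requires_positive_blood(self):
        with pytest.raises(QuantifyError):
            vp.tbr(1.0, 0.0)

    def test_corrected_suv_hand_values(self):
        assert vp.corrected_suv(2.2, 1.1) == pytest.approx(1.1)
        assert vp.corrected_suv(1.1, 1.1) == 0.0
        assert vp.corrected_suv(0.9, 1.1) == pytest.approx(-0.2)

    @settings(deadline=None, max_examples=200)
    @given(s=st.floats(0.01, 50), b=st.floats(0.01, 10))
    def test_tbr_csuv_identity(self, s, b):
        assert vp.tbr(vp.corrected_suv(s, b) + b, b) == pytest.approx(s / b)

    def test_suv_helper(self):
        assert vp.suv_from_activity(5e3, 125e6, 75e3) == pytest.approx(3.0)
        with pytest.raises(QuantifyError):
            vp.suv_from_activity(1.0, 0.0, 70e3)


class TestQuantifyValve:
    def _uniform_setup(self, v=2.0, n=4):
        stack = _toy_stack([np.full((9, 9), v)] * n)
        disc = np.ones((9, 9), bool)
        rois = RoiSet({k: disc for k in range(n)},
                      {}, {c: {k: disc for k in range(n)}
                           for c in ("right", "noncoronary", "left")})
        return stack, rois

    def test_uniform_field_analytics(self):
        stack, rois = self._uniform_setup(v=2.0)
        bp = vp.BloodPool("right_atrium", 0.8, [0.8, 0.8])
        res = vp.quantify_valve(stack, rois, bp)
        for m in ("suv_mean", "suv_max", "suv_mds_mean", "suv_mds_max"):
            assert getattr(res, m) == pytest.approx(2.0)
            assert getattr(res, m.replace("suv", "tbr", 1)) == pytest.approx(2.5)
            assert getattr(res, m.replace("suv", "csuv", 1)) == pytest.approx(1.2)
        assert not res.negative_csuv

    def test_scale_invariance_of_tbr(self):
        stack, rois = self._uniform_setup(v=2.0)
        res1 = vp.quantify_valve(stack, rois, vp.BloodPool("right_atrium", 0.8, [0.8] * 2))
        stack2, _ = self._uniform_setup(v=6.0)
        res2 = vp.quantify_valve(stack2, rois, vp.BloodPool("right_atrium", 2.4, [2.4] * 2))
        assert res2.tbr_mds_mean == pytest.approx(res1.tbr_mds_mean)
        assert res2.suv_mds_mean == pytest.approx(3.0 * res1.suv_mds_mean)

    def test_negative_csuv_flagged(self):
        stack, rois = self._uniform_setup(v=0.9)
        res = vp.quantify_valve(stack, rois, vp.BloodPool("right_atrium", 1.1, [1.1] * 2))
        assert res.negative_csuv
        assert res.csuv_mean == pytest.approx(-0.2)


class TestCuspFlags:
    def test_all_sectors_at_blood_level_negative(self):
        stack, rois = TestQuantifyValve()._uniform_setup(v=1.1)
        bp = vp.BloodPool("right_atrium", 1.1, [1.1, 1.1])
        flags = vp.cusp_uptake_flags(stack, rois.cusp_masks, bp)
        assert flags == {"right": False, "noncoronary": False, "left": False}

    def test_lesion_sector_flagged(self):
        slices = [np.full((9, 9), 1.0) for _ in range(3)]
        slices[1][2, 2] = 2.0  # lesion at 2x blood pool
        stack = _toy_stack(slices)
        disc = np.ones((9, 9), bool)
        right = np.zeros((9, 9), bool)
        right[:4, :4] = True
        other = disc & ~right
        left = other.copy(); left[:, 5:] = False
        non = other & ~left
        rois_cusp = {"right": {k: right for k in range(3)},
                     "left": {k: left for k in range(3)},
                     "noncoronary": {k: non for k in range(3)}}
        bp = vp.BloodPool("right_atrium", 1.0, [1.0, 1.0])
        flags = vp.cusp_uptake_flags(stack, rois_cusp, bp)
        assert flags == {"right": True, "left": False, "noncoronary": False}

    def test_phantom_lesion_placement_recovered(self):
        cfg = vp.PhantomConfig.ideal(lesions=(
            vp.Lesion("cusp-body", "right", 3.0, 2.0),
            vp.Lesion("cusp-body", "noncoronary", 2.6, 2.0)))
        series, truth = vp.generate_phantom(cfg, scan_index=1)
        run = vp.RunConfig(slice_thickness_mm=2.0, roi_level_jitter_mm=0.0)
        res = vp.analyze_scan(series, truth, run)["right_atrium"]
        assert res.cusp_flags == {"right": True, "left": False, "noncoronary": True}
        assert res.cusp_flags == truth.cusp_flags

    def test_missing_sector_rejected(self):
        stack = _toy_stack([np.ones((4, 4))])
        with pytest.raises(QuantifyError):
            vp.cusp_uptake_flags(stack, {"right": {}},
                                 vp.BloodPool("right_atrium", 1.0, [1, 1]))


class TestMDSSelectionType:
    def test_pairs_are_contiguous(self, rng):
        for _ in range(50):
            prof = rng.random(int(rng.integers(2, 10)))
            mds = vp.mds_uptake(_stats(prof))
            assert mds.mean_pair[1] == mds.mean_pair[0] + 1
            assert mds.max_pair[1] == mds.max_pair[0] + 1
            assert isinstance(mds, MDSSelection)
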