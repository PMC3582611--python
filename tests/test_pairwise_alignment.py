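import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

import mipstitch as ms
from mipstitch.pairwise_alignment import MIP_MAPS
from conftest import SMALL_ALIGN, ncc_bruteforce


def _tile(nominal_v=0, nominal_h=0, nominal_d=0, row=0, col=0):
    return ms.Tile(row=row, col=col, nominal_v=nominal_v, nominal_h=nominal_h,
                   nominal_d=nominal_d)


class TestOverlapRois:
    def test_nominal_overlap_width(self):
        a, b = _tile(), _tile(nominal_h=412, col=1)
        roi_a, roi_b = ms.compute_overlap_rois(a, b, "H", (512, 512, 100))
        assert roi_a[1] == (412, 512) and roi_b[1] == (0, 100)
        assert roi_a[0] == roi_b[0] == (0, 512)

    def test_coincident_tiles_overlap_fully(self):
        a, b = _tile(), _tile(col=1)
        roi_a, roi_b = ms.compute_overlap_rois(a, b, "H", (64, 64, 10))
        assert roi_a == roi_b == ((0, 64), (0, 64), (0, 10))

    def test_no_overlap_is_an_error(self):
        a, b = _tile(), _tile(nominal_h=512, col=1)
        with pytest.raises(ms.StitchError, match="no overlap"):
            ms.compute_overlap_rois(a, b, "H", (512, 512, 100))

    def test_equal_shapes_under_cross_axis_offset(self):
        # tiles of one row rarely share the exact V position
        a, b = _tile(), _tile(nominal_v=7, nominal_h=40, col=1)
        roi_a, roi_b = ms.compute_overlap_rois(a, b, "H", (64, 64, 10), 5)
        shape_a = tuple(hi - lo for lo, hi in roi_a)
        shape_b = tuple(hi - lo for lo, hi in roi_b)
        assert shape_a == shape_b
        assert roi_a[0] == (7, 64) and roi_b[0] == (0, 57)


class TestMip:
    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 255, size=(6, 5, 4)).astype(np.uint8)
        for axis_name, axis in (("V", 0), ("H", 1), ("D", 2)):
            got = ms.mip(arr, axis_name)
            shape = tuple(s for i, s in enumerate(arr.shape) if i != axis)
            expect = np.zeros(shape, dtype=arr.dtype)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    for k in range(arr.shape[2]):
                        idx = tuple(x for n, x in enumerate((i, j, k)) if n != axis)
                        expect[idx] = max(expect[idx], arr[i, j, k])
            assert np.array_equal(got, expect)

    def test_single_bright_voxel(self):
        arr = np.zeros((4, 5, 6), dtype=np.uint8)
        arr[1, 2, 3] = 255
        proj = ms.mip(arr, "D")
        assert proj[1, 2] == 255 and proj.sum() == 255

    def test_all_zero(self):
        assert ms.mip(np.zeros((3, 3, 3)), "V").max() == 0


class TestNccMap:
    def test_self_correlation_peaks_at_origin(self):
        img = np.random.default_rng(1).random((20, 20))
        m = ms.ncc_map(img, img, 3)
        assert m.peak_shift == (0, 0)
        assert m.peak_value == pytest.approx(1.0)

    def test_translation_recovered(self):
        rng = np.random.default_rng(2)
        a = gaussian_filter(rng.random((40, 40)), 1.0)
        b = np.zeros_like(a)
        b[1:, :-2] = a[:-1, 2:]  # b is a translated by (1, -2)
        m = ms.ncc_map(a, b, 4)
        assert m.peak_shift == (1, -2)
        assert m.peak_value > 0.95

    def test_constant_images_flagged_degenerate(self):
        c = np.full((15, 15), 7.0)
        m = ms.ncc_map(c, c, 3)
        assert m.degenerate
        assert not m.values.any()

    def test_zero_variance_shift_scores_zero(self):
        a = np.full((15, 15), 3.0)
        b = np.random.default_rng(3).random((15, 15))
        m = ms.ncc_map(a, b, 2)
        assert not m.degenerate
        assert not m.values.any()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            a, b = rng.random((16, 16)), rng.random((16, 16))
            got = ms.ncc_map(a, b, 3).values
            assert np.abs(got - ncc_bruteforce(a, b, 3)).max() < 1e-10

    def test_shape_too_small_for_window(self):
        with pytest.raises(ms.ValidationError):
            ms.ncc_map(np.ones((6, 20)), np.ones((6, 20)), 3)


class TestPeakAndWidth:
    def test_delta_peak_has_unit_widths(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        shift, value, widths = ms.peak_and_width(vals)
        assert shift == (0, 0) and value == 1.0 and widths == (1, 1)

    def test_flat_map_tie_breaks_to_center(self):
        vals = np.full((9, 9), 0.5)
        shift, value, widths = ms.peak_and_width(vals)
        assert shift == (0, 0)
        assert widths == (9, 9)

    def test_gaussian_bump_widths_match_scan_oracle(self):
        delta, sigma = 6, 1.8
        u = np.arange(-delta, delta + 1)
        vals = np.exp(-(u[:, None] ** 2 + u[None, :] ** 2) / (2 * sigma**2))
        shift, peak, widths = ms.peak_and_width(vals, width_fraction=0.75)
        assert shift == (0, 0)
        thr = 0.75 * peak
        row = vals[delta, :]
        expect = 0
        for k in range(len(row)):
            if row[k] >= thr:
                expect += 1  # bump is unimodal, so the run is contiguous
        assert widths == (expect, expect)

    def test_tie_prefers_smaller_shift(self):
        vals = np.zeros((7, 7))
        vals[3, 4] = vals[1, 1] = 0.9  # shifts (0,1) and (-2,-2)
        shift, _, _ = ms.peak_and_width(vals)
        assert shift == (0, 1)


class TestReliability:
    def test_best_case(self):
        assert ms.reliability(1.0, 1, 21) == 1.0

    def test_nonpositive_peak_is_unreliable(self):
        assert ms.reliability(0.0, 1, 21) == 0.0
        assert ms.reliability(-0.8, 3, 21) == 0.0

    def test_full_width_is_unreliable(self):
        assert ms.reliability(0.9, 21, 21) == 0.0

    @given(
        peak=st.floats(-1, 1),
        w1=st.integers(1, 21),
        w2=st.integers(1, 21),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_monotone_in_width_and_peak(self, peak, w1, w2):
        lo, hi = sorted((w1, w2))
        r_narrow = ms.reliability(peak, lo, 21)
        r_wide = ms.reliability(peak, hi, 21)
        assert 0.0 <= r_wide <= r_narrow <= 1.0
        if peak < 1:
            assert ms.reliability(1.0, lo, 21) >= ms.reliability(peak, lo, 21)


class TestAlignSubstackPair:
    @staticmethod
    def _textured(shape, seed):
        rng = np.random.default_rng(seed)
        return gaussian_filter(rng.random(shape), 1.0)

    def test_six_candidates_two_per_direction(self):
        sub = self._textured((30, 30, 30), 0)
        out = ms.align_substack_pair(sub, sub, "H", ms.AlignConfig(delta_search=4))
        assert len(out.candidates) == 6
        for d in "VHD":
            assert sum(c.direction == d for c in out.candidates) == 2
        assert {c.mip_axis for c in out.candidates} == {"V", "H", "D"}
        assert [m[0] for m in MIP_MAPS] == ["D", "V", "H"]

    def test_identical_substacks_recover_zero(self):
        sub = self._textured((30, 30, 30), 1)
        out = ms.align_substack_pair(sub, sub, "H", ms.AlignConfig(delta_search=4))
        for d in "VHD":
            assert out.best[d].offset == 0
            assert out.best[d].reliability > 0.9

    @pytest.mark.parametrize("true_shift", [(2, -1, 3), (-3, 0, -2)])
    def test_known_shift_recovered(self, true_shift):
        """A substack cropped ``true_shift`` further into the same scene must
        report exactly that offset (the jitter difference of the tiles)."""
        base = self._textured((60, 60, 60), 2)
        t = true_shift
        sub_a = base[10:40, 10:40, 10:40]
        sub_b = base[10 + t[0] : 40 + t[0], 10 + t[1] : 40 + t[1], 10 + t[2] : 40 + t[2]]
        out = ms.align_substack_pair(sub_a, sub_b, "H", ms.AlignConfig(delta_search=5))
        assert tuple(out.best[d].offset for d in "VHD") == true_shift

    def test_pure_noise_is_unreliable(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((24, 24, 24)), rng.random((24, 24, 24))
        out = ms.align_substack_pair(a, b, "H", ms.AlignConfig(delta_search=4))
        assert all(c.reliability < 0.5 for c in out.candidates)

    def test_constant_overlap_degenerates_gracefully(self):
        c = np.full((20, 20, 20), 5.0)
        out = ms.align_substack_pair(c, c, "V", ms.AlignConfig(delta_search=3))
        for d in "VHD":
            assert out.best[d].offset == 0
            assert out.best[d].reliability == 0.0


class TestAlignVolume:
    def test_record_counting(self, aligned_state):
        # 2x2 grid -> 4 pairs; 40 slices at n_slices=20 -> 2 layers each
        assert len(aligned_state.pair_displacements) == 4
        for records in aligned_state.pair_displacements.values():
            assert len(records) == 2
            assert [(pd.z0, pd.z1) for pd in records] == [(0, 20), (20, 40)]

    def test_recovers_ground_truth_within_one_voxel(self, small, projected_state):
        truth = small["truth"]
        for key, pd in projected_state.pair_displacements.items():
            true = truth.true_pair_displacement(key)
            assert all(abs(e - t) <= 1 for e, t in zip(pd.offsets, true))

    def test_preview_slice_range(self, small):
        st = ms.align_volume(
            small["volume"], SMALL_ALIGN, slice_range=(20, 40)
        )
        for records in st.pair_displacements.values():
            assert [(pd.z0, pd.z1) for pd in records] == [(20, 40)]

    def test_empty_selection_rejected(self, small):
        with pytest.raises(ms.ValidationError):
            ms.align_volume(small["volume"], SMALL_ALIGN, row_range=(1, 1))

    def test_memory_and_read_once_contracts(self, tmp_path):
        """3x4 grid: peak resident substacks is min{3,4}+1 = 4 and every
        slice file is opened exactly once."""
        phantom = ms.make_phantom((60, 80, 10), content_density=4.0, seed=6)
        vol, _ = ms.tile_phantom(
            phantom, 3, 4, (24, 24, 6), (10, 10), 2, 2.0, seed=7,
            out_path=tmp_path / "grid34",
        )
        counters = ms.Counters()
        st = ms.align_volume(
            vol, ms.AlignConfig(n_slices=6, delta_search=2), counters=counters
        )
        assert counters.peak_resident_substacks == 4
        assert counters.max_opens_per_file == 1
        assert counters.total_opens == 3 * 4 * 6
        assert len(st.pair_displacements) == 3 * 3 + 2 * 4
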