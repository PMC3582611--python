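import numpy as np
import pytest

import mipstitch as ms


class TestBlendWeights:
    def test_endpoints_and_midpoint(self):
        assert ms.blend_weights(0.0) == (1.0, 0.0)
        assert ms.blend_weights(1.0)[0] == pytest.approx(0.0, abs=1e-15)
        assert ms.blend_weights(0.5)[0] == pytest.approx(0.5)

    def test_weights_sum_to_one(self):
        t = np.linspace(0, 1, 10_000)
        w1, w2 = ms.blend_weights(t)
        assert np.abs(w1 + w2 - 1.0).max() < 1e-12
        assert (np.diff(w1) <= 0).all()  # monotone decreasing


class TestFusePairRegion:
    def test_constant_inputs_are_preserved(self):
        a = np.full((5, 8), 42.0)
        assert np.allclose(ms.fuse_pair_region(a, a, axis=1), 42.0)

    def test_three_pixel_ramp(self):
        a = np.zeros((1, 3))
        b = np.full((1, 3), 100.0)
        fused = ms.fuse_pair_region(a, b, axis=1)
        assert fused[0].tolist() == [0.0, 50.0, 100.0]

    def test_no_blending_hard_cut(self):
        a = np.zeros((2, 4))
        b = np.full((2, 4), 9.0)
        fused = ms.fuse_pair_region(a, b, axis=1, blending="none")
        assert np.array_equal(fused, np.array([[0, 0, 9, 9]] * 2, dtype=float))

    def test_convexity(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((6, 10)) * 200, rng.random((6, 10)) * 200
        fused = ms.fuse_pair_region(a, b, axis=0)
        assert (fused >= np.minimum(a, b) - 1e-9).all()
        assert (fused <= np.maximum(a, b) + 1e-9).all()

    def test_shape_mismatch(self):
        with pytest.raises(ms.ValidationError):
            ms.fuse_pair_region(np.ones((2, 3)), np.ones((2, 4)), axis=1)


class TestDownsample:
    def test_eight_voxel_mean(self):
        block = np.arange(8, dtype=float).reshape(2, 2, 2)
        assert ms.downsample_once(block)[0, 0, 0] == 3.5

    def test_constant_volume_stays_constant(self):
        v = np.full((8, 6, 4), 17.0)
        for _ in range(2):
            v = ms.downsample_once(v)
            assert (v == 17.0).all()

    def test_voxel_count_ratio_even_dims(self):
        v = np.zeros((8, 6, 4))
        assert ms.downsample_once(v).size * 8 == v.size

    def test_odd_dims_partial_blocks(self):
        rng = np.random.default_rng(1)
        v = rng.random((5, 4, 3))
        out = ms.downsample_once(v)
        assert out.shape == (3, 2, 2)
        # brute-force partial-block means
        for i in range(3):
            for j in range(2):
                for k in range(2):
                    blk = v[2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * k : 2 * k + 2]
                    assert out[i, j, k] == pytest.approx(blk.mean())

    def test_mean_preserving_for_even_dims(self):
        rng = np.random.default_rng(2)
        v = rng.random((16, 8, 8)) * 255
        assert ms.downsample_once(v).mean() == pytest.approx(v.mean())


class TestFuseSliceGroup:
    def test_single_tile_grid_is_identity(self, tmp_path):
        phantom = ms.make_phantom((40, 40, 12), content_density=2.0, seed=4)
        vol, _ = ms.tile_phantom(
            phantom, 1, 1, (32, 32, 8), (8, 8), 0, 0.0, seed=5,
            out_path=tmp_path / "one",
        )
        st = ms.StitchState(
            stage="placed", volume=vol,
            pair_displacements={},
            placements={(0, 0): (0, 0, 0)},
        )
        fused = ms.fuse_slice_group(st, range(8))
        tile = ms.load_substack(vol, ms.SubstackRef(vol.tile(0, 0), 0, 8))
        assert np.array_equal(np.stack([f.data for f in fused], axis=-1), tile)

    def test_clean_volume_fuses_to_phantom_exactly(self, clean, clean_placed):
        """jitter 0, noise 0, blending on: blending identical data is the
        identity, so the fused volume equals the phantom crop everywhere."""
        fused = ms.fuse_slice_group(clean_placed, range(20))
        block = np.stack([f.data for f in fused], axis=-1)
        assert np.array_equal(block, clean["phantom"][0:84, 0:84, 0:20])

    def test_jittered_volume_matches_phantom_off_seams(self, small, placed_state):
        """Full-pipeline recovery: away from a +-1 voxel band around overlap
        seams, the fused image equals the phantom (up to tile noise)."""
        phantom = small["phantom"].astype(float)
        truth = small["truth"]
        lo = np.min(np.stack([np.array(v) for v in truth.true_position.values()]), 0)
        fused = ms.fuse_slice_group(placed_state, range(5, 10))
        margin = 3  # jitter_max margin used when cropping tiles from the phantom
        pv, ph, pd = placed_state.placements[(0, 0)]
        for fs in fused:
            # interior of tile (0,0): no overlap, no seam; noise sigma 6
            crop = phantom[
                margin + lo[0] + pv : margin + lo[0] + pv + 40,
                margin + lo[1] + ph : margin + lo[1] + ph + 40,
                margin + lo[2] + fs.z,
            ]
            region = fs.data[pv : pv + 40, ph : ph + 40].astype(float)
            diff = np.abs(region - crop)
            assert diff.mean() < 6.0

    def test_hard_seam_without_blending(self, tmp_path, hierarchy_writer):
        """Two constant tiles, blending off: the fused slice jumps at the
        overlap midpoint; with blending the transition is gradual."""
        dark = np.full((16, 16, 4), 10, dtype=np.uint8)
        bright = np.full((16, 16, 4), 200, dtype=np.uint8)
        root = hierarchy_writer(
            tmp_path / "two", {(0, 0): dark, (0, 1): bright}, step_v=8, step_h=8
        )
        vol = ms.import_volume(root)
        st = ms.StitchState(
            stage="placed", volume=vol, pair_displacements={},
            placements={(0, 0): (0, 0, 0), (0, 1): (0, 8, 0)},
        )
        hard = ms.fuse_slice_group(st, [0], ms.MergeConfig(blending="none"))[0].data
        # overlap columns 8..16, midpoint at column 12
        assert (hard[:, :12] == 10).all() and (hard[:, 12:] == 200).all()
        soft = ms.fuse_slice_group(st, [0], ms.MergeConfig())[0].data
        mids = soft[0, 8:16]
        assert (np.diff(mids.astype(int)) >= 0).all()
        assert ((mids > 10) & (mids < 200)).any()

    def test_intensity_conservation_in_overlaps(self, clean, clean_placed):
        fused = ms.fuse_slice_group(clean_placed, [3])[0].data
        ph = clean["phantom"]
        assert fused.min() >= ph.min() and fused.max() <= ph.max()


class TestWritePyramid:
    def test_level_zero_matches_fuse_slice_group(self, clean_placed, tmp_path):
        out = ms.write_pyramid(
            clean_placed, ms.MergeConfig(n_levels=0), tmp_path / "flat"
        )
        lvl0 = ms.import_volume(out / "RES(84x84x20)")
        arr = ms.load_substack(lvl0, ms.SubstackRef(lvl0.tile(0, 0), 0, 20))
        fused = ms.fuse_slice_group(clean_placed, range(20))
        assert np.array_equal(arr, np.stack([f.data for f in fused], axis=-1))

    def test_every_level_written_and_mean_preserved(self, clean_placed, tmp_path):
        out = ms.write_pyramid(
            clean_placed, ms.MergeConfig(n_levels=2), tmp_path / "pyr"
        )
        names = sorted(p.name for p in out.iterdir())
        assert names == ["RES(21x21x5)", "RES(42x42x10)", "RES(84x84x20)"]
        l0 = ms.import_volume(out / "RES(84x84x20)")
        l2 = ms.import_volume(out / "RES(21x21x5)")
        a0 = ms.load_substack(l0, ms.SubstackRef(l0.tile(0, 0), 0, 20))
        a2 = ms.load_substack(l2, ms.SubstackRef(l2.tile(0, 0), 0, 5))
        assert a2.mean() == pytest.approx(a0.mean(), abs=1.0)

    def test_multistack_layout_counts(self, clean_placed, tmp_path):
        cfg = ms.MergeConfig(
            n_levels=0, output_layout="multi_stack", multistack_dims=(42, 42)
        )
        out = ms.write_pyramid(clean_placed, cfg, tmp_path / "multi")
        lvl = out / "RES(84x84x20)"
        stacks = [d for v in sorted(lvl.iterdir()) for d in sorted(v.iterdir())]
        assert len(stacks) == 4  # 84x84 footprint in 42x42 sub-stacks
        sub = ms.import_volume(lvl)
        assert (sub.n_rows, sub.n_cols) == (2, 2)

    def test_refuses_nonempty_output(self, clean_placed, tmp_path):
        out = tmp_path / "occupied"
        out.mkdir()
        (out / "junk.txt").write_text("hello")
        with pytest.raises(ms.StitchError, match="not empty"):
            ms.write_pyramid(clean_placed, ms.MergeConfig(n_levels=0), out)
        ms.write_pyramid(
            clean_placed, ms.MergeConfig(n_levels=0), out, overwrite=True
        )

    def test_group_size_and_memory_contract(self, placed_state, tmp_path):
        counters = ms.Counters()
        ms.write_pyramid(
            placed_state, ms.MergeConfig(n_levels=3), tmp_path / "mem",
            counters=counters,
        )
        assert ms.MergeConfig(n_levels=3).group_size == 8
        assert counters.peak_resident_fused_slices <= 8

    def test_preview_slice_range(self, clean_placed, tmp_path):
        out = ms.write_pyramid(
            clean_placed, ms.MergeConfig(n_levels=0), tmp_path / "prev",
            slice_range=(4, 8),
        )
        lvl = ms.import_volume(out / "RES(84x84x4)")
        assert lvl.n_slices_total == 4
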