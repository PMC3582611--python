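import numpy as np
import pytest
import tifffile

import mipstitch as ms

# Conditions of the small shared fixture: a 2x2 grid dense enough in
# structure that every overlap band carries alignment signal.
SMALL = dict(
    n_rows=2,
    n_cols=2,
    tile_shape=(64, 64, 40),
    overlap_vh=(16, 16),
    jitter_max=3,
    noise_sigma=6.0,
    content_density=4.0,
)
SMALL_ALIGN = ms.AlignConfig(n_slices=20, delta_search=7)


@pytest.fixture(scope="session")
def small(tmp_path_factory):
    """Jittered, noisy 2x2 synthetic volume with ground truth."""
    root = tmp_path_factory.mktemp("small") / "vol"
    volume, truth, phantom = ms.make_benchmark_hierarchy(root, seed=42, **SMALL)
    return {"volume": volume, "truth": truth, "phantom": phantom, "root": root}


@pytest.fixture(scope="session")
def clean(tmp_path_factory):
    """Jitter-free, noise-free 2x2 volume: every fused voxel is predictable."""
    root = tmp_path_factory.mktemp("clean") / "vol"
    volume, truth, phantom = ms.make_benchmark_hierarchy(
        root, seed=3, n_rows=2, n_cols=2, tile_shape=(48, 48, 20),
        overlap_vh=(12, 12), jitter_max=0, noise_sigma=0.0, content_density=4.0,
    )
    return {"volume": volume, "truth": truth, "phantom": phantom, "root": root}


@pytest.fixture(scope="session")
def aligned_state(small):
    return ms.align_volume(small["volume"], SMALL_ALIGN)


@pytest.fixture(scope="session")
def projected_state(aligned_state):
    return ms.project_state(aligned_state)


@pytest.fixture(scope="session")
def placed_state(projected_state):
    st = ms.threshold_state(projected_state, ms.ThresholdConfig(0.7))
    return ms.solve_placement(st)


@pytest.fixture(scope="session")
def clean_placed(clean):
    st = ms.align_volume(clean["volume"], ms.AlignConfig(n_slices=20, delta_search=5))
    st = ms.project_state(st)
    st = ms.threshold_state(st, ms.ThresholdConfig(0.7))
    return ms.solve_placement(st)


def make_descriptor_volume(n_rows, n_cols, tile_shape=(64, 64, 40), overlap=(16, 16)):
    """A metadata-only volume (no slice files) for selection/placement tests."""
    tv, th, td = tile_shape
    tiles = {
        (r, c): ms.Tile(
            row=r, col=c,
            nominal_v=r * (tv - overlap[0]),
            nominal_h=c * (th - overlap[1]),
            nominal_d=0,
        )
        for r in range(n_rows)
        for c in range(n_cols)
    }
    from pathlib import Path

    return ms.TiledVolume(
        n_rows=n_rows, n_cols=n_cols,
        tile_height_v=tv, tile_width_h=th, n_slices_total=td,
        voxel_size=(1.0, 1.0, 1.0), tiles=tiles,
        root_path=Path("/nonexistent"),
    )


@pytest.fixture
def descriptor_volume():
    return make_descriptor_volume


def write_hierarchy(root, tile_arrays, step_v, step_h):
    """Write explicit per-tile 3D arrays as an importable hierarchy."""
    for (r, c), arr in tile_arrays.items():
        v_t, h_t = r * step_v * 10, c * step_h * 10
        tdir = root / f"{v_t:06d}" / f"{v_t:06d}_{h_t:06d}"
        tdir.mkdir(parents=True, exist_ok=True)
        for z in range(arr.shape[2]):
            tifffile.imwrite(
                tdir / f"{v_t:06d}_{h_t:06d}_{z * 10:06d}.tif", arr[:, :, z]
            )
    return root


@pytest.fixture
def hierarchy_writer():
    return write_hierarchy


def ncc_bruteforce(img_a, img_b, delta):
    """Independent quadruple-loop NCC oracle (explicit shift/pixel loops)."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    n0, n1 = a.shape
    side = 2 * delta + 1
    out = np.zeros((side, side))
    for u in range(-delta, delta + 1):
        for v in range(-delta, delta + 1):
            xs = [x for x in range(n0) if 0 <= x + u < n0]
            ys = [y for y in range(n1) if 0 <= y + v < n1]
            av = [a[x][y] for x in xs for y in ys]
            bv = [b[x + u][y + v] for x in xs for y in ys]
            ma = sum(av) / len(av)
            mb = sum(bv) / len(bv)
            num = sum((p - ma) * (q - mb) for p, q in zip(av, bv))
            da = sum((p - ma) ** 2 for p in av)
            db = sum((q - mb) ** 2 for q in bv)
            out[u + delta][v + delta] = (
                num / (da * db) ** 0.5 if da > 0 and db > 0 else 0.0
            )
    return out
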