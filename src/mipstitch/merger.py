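"""Streaming fusion of placed tiles and multiresolution pyramid output.

Final slices are assembled stripe-by-stripe: within a tile row, adjacent
tiles are fused along H; each finished row stripe is then fused into the
accumulated slice along V.  Non-overlapping pixels are verbatim copies; in
an overlap the two contributions are combined with two sinusoidal weights
phase-shifted by pi (w1 + w2 = 1), running across the full overlap width,
so the seam fades smoothly from one tile to the other.  Four-tile corners
receive the product of the H and V weights because the two fusion passes
compose.  Disabling blending replaces the ramp with a hard cut at the
overlap midpoint, which makes residual misalignments visible for manual
inspection.

The fused image is written as a multiresolution pyramid: each coarser level
is the mean of 2x2x2 blocks of the finer one (partial blocks at odd edges
average the available voxels).  The volume is processed in groups of
2**n_levels slices (32 for the usual 5 levels), so one group of fused
slices plus one tile row's slices bound the resident memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .instrumentation import Counters
from .volume_model import (
    StitchError,
    StitchState,
    SubstackRef,
    ValidationError,
    load_substack,
)

__all__ = [
    "MergeConfig",
    "FusedSlice",
    "blend_weights",
    "fuse_pair_region",
    "fuse_slice_group",
    "downsample_once",
    "write_pyramid",
]


@dataclass(frozen=True)
class MergeConfig:
    """Merging and pyramid parameters.

    ``n_levels`` halving steps (the coarsest level is reduced 2**n_levels
    per axis and one slice group spans 2**n_levels slices); ``blending``
    'sinusoidal' or 'none'; single-stack output or a multi-stack mosaic of
    ``multistack_dims``-sized (V, H) sub-stacks for selective access.
    """

    n_levels: int = 5
    blending: str = "sinusoidal"
    output_layout: str = "single_stack"
    multistack_dims: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.n_levels < 0:
            raise ValidationError("n_levels must be >= 0")
        if self.blending not in ("sinusoidal", "none"):
            raise ValidationError("blending must be 'sinusoidal' or 'none'")
        if self.output_layout not in ("single_stack", "multi_stack"):
            raise ValidationError("output_layout must be 'single_stack' or 'multi_stack'")

    @property
    def group_size(self) -> int:
        return 2**self.n_levels


@dataclass
class FusedSlice:
    """One slice of the final image footprint, in the input dtype."""

    data: np.ndarray
    z: int


def blend_weights(t):
    """Complementary sinusoidal weights at normalized position t in [0, 1].

    w1 = (1 + cos(pi t))/2 falls from 1 to 0; w2 = 1 - w1 rises; their sum
    is identically 1 so blending never leaves the intensity range.
    """
    t = np.asarray(t, dtype=np.float64)
    w1 = (1.0 + np.cos(np.pi * t)) / 2.0
    return w1, 1.0 - w1


def _weight_profile(n: int, blending: str) -> np.ndarray:
    """Weight of the *first* (earlier) image across an n-pixel overlap."""
    if n == 1:
        t = np.array([0.5])
    else:
        t = np.arange(n) / (n - 1)
    if blending == "sinusoidal":
        return blend_weights(t)[0]
    return (np.arange(n) < n / 2).astype(np.float64)  # hard cut at midpoint


def fuse_pair_region(
    region_a: np.ndarray,
    region_b: np.ndarray,
    axis: int,
    blending: str = "sinusoidal",
) -> np.ndarray:
    """Blend two equally shaped overlap regions along ``axis``.

    The normalized position t runs from the a-side (t=0, a fully weighted)
    to the b-side (t=1); returns a float array.
    """
    a = np.asarray(region_a, dtype=np.float64)
    b = np.asarray(region_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"region shapes differ: {a.shape} vs {b.shape}")
    w1 = _weight_profile(a.shape[axis], blending)
    shape = [1] * a.ndim
    shape[axis] = a.shape[axis]
    w1 = w1.reshape(shape)
    return w1 * a + (1.0 - w1) * b


def _composite(
    canvas: np.ndarray,
    mask: np.ndarray,
    plane: np.ndarray,
    plane_mask: np.ndarray | None,
    origin: tuple[int, int],
    axis: int,
    blending: str,
) -> None:
    """Fuse ``plane`` into ``canvas`` at ``origin``, blending along ``axis``.

    The overlap is the intersection of the bounding intervals, along the
    blend axis, of the existing and the incoming coverage; within it,
    pixels covered by both are mixed with the weight ramp (earlier content
    weighted 1 at the low end), pixels covered by one side are copied.
    """
    v0, h0 = origin
    sv, sh = plane.shape
    sl = (slice(v0, v0 + sv), slice(h0, h0 + sh))
    sub = canvas[sl]
    msub = mask[sl]
    if plane_mask is None:
        plane_mask = np.ones(plane.shape, dtype=bool)
    result = np.where(plane_mask, plane.astype(np.float64), sub)

    cov_old = msub.any(axis=1 - axis)
    cov_new = plane_mask.any(axis=1 - axis)
    if cov_old.any() and cov_new.any():
        lo = max(int(np.argmax(cov_old)), int(np.argmax(cov_new)))
        hi = min(
            len(cov_old) - int(np.argmax(cov_old[::-1])),
            len(cov_new) - int(np.argmax(cov_new[::-1])),
        )
        if hi > lo:
            w_old = _weight_profile(hi - lo, blending)
            shape = [1, 1]
            shape[axis] = hi - lo
            w_old = w_old.reshape(shape)
            ovsl = [slice(None), slice(None)]
            ovsl[axis] = slice(lo, hi)
            ovsl = tuple(ovsl)
            mixed = w_old * sub[ovsl] + (1.0 - w_old) * plane[ovsl]
            both = msub[ovsl] & plane_mask[ovsl]
            result[ovsl] = np.where(both, mixed, result[ovsl])
    canvas[sl] = result
    mask[sl] |= plane_mask


def _footprint(state: StitchState, rows, cols):
    place = state.placements
    vol = state.volume
    sel = [(r, c) for r in rows for c in cols]
    v_lo = min(place[k][0] for k in sel)
    h_lo = min(place[k][1] for k in sel)
    v_hi = max(place[k][0] for k in sel) + vol.tile_height_v
    h_hi = max(place[k][1] for k in sel) + vol.tile_width_h
    d_lo = min(place[k][2] for k in sel)
    d_hi = max(place[k][2] for k in sel) + vol.n_slices_total
    return (v_lo, v_hi), (h_lo, h_hi), (d_lo, d_hi)


def fuse_slice_group(
    state: StitchState,
    z_group,
    config: MergeConfig | None = None,
    row_range: tuple[int, int] | None = None,
    col_range: tuple[int, int] | None = None,
    counters: Counters | None = None,
) -> list[FusedSlice]:
    """Fuse the placed tiles into final slices for the given global z indices.

    Tiles are read one row at a time (the required slices only); each row is
    fused along H into a stripe and the stripe fused along V into the
    accumulating slices, honoring every tile's D placement.  Tiles not
    covering a z contribute background (zero).
    """
    state.require_stage("placed")
    config = config or MergeConfig()
    counters = counters if counters is not None else Counters()
    vol = state.volume
    rows = range(*(row_range or (0, vol.n_rows)))
    cols = range(*(col_range or (0, vol.n_cols)))
    z_group = list(z_group)
    if not z_group:
        raise ValidationError("empty slice group")
    (v_lo, v_hi), (h_lo, h_hi), _ = _footprint(state, rows, cols)
    fv, fh = v_hi - v_lo, h_hi - h_lo

    canvases = {z: np.zeros((fv, fh), dtype=np.float64) for z in z_group}
    masks = {z: np.zeros((fv, fh), dtype=bool) for z in z_group}
    counters.fused_slices_resident(len(z_group))

    for r in rows:
        # load only the slices of this row needed for the group
        row_data: dict[int, tuple[np.ndarray, int]] = {}
        n_planes = 0
        for c in cols:
            d = state.placements[(r, c)][2]
            locals_ = [z - d for z in z_group if 0 <= z - d < vol.n_slices_total]
            if not locals_:
                continue
            lo, hi = min(locals_), max(locals_) + 1
            arr = load_substack(vol, SubstackRef(vol.tile(r, c), lo, hi), counters)
            row_data[c] = (arr, lo)
            n_planes += arr.shape[2]
        counters.tile_slices_resident(n_planes)

        for z in z_group:
            stripe = np.zeros((fv, fh), dtype=np.float64)
            smask = np.zeros((fv, fh), dtype=bool)
            for c in cols:
                if c not in row_data:
                    continue
                pv, ph, pd = state.placements[(r, c)]
                if not (0 <= z - pd < vol.n_slices_total):
                    continue
                arr, lo = row_data[c]
                plane = arr[:, :, z - pd - lo]
                _composite(
                    stripe, smask, plane, None,
                    (pv - v_lo, ph - h_lo), axis=1, blending=config.blending,
                )
            if smask.any():
                _composite(
                    canvases[z], masks[z], stripe, smask,
                    (0, 0), axis=0, blending=config.blending,
                )
        del row_data
        counters.tile_slices_resident(0)

    info = np.iinfo(np.dtype(vol.dtype))
    out = []
    for z in z_group:
        data = np.clip(np.rint(canvases[z]), info.min, info.max).astype(vol.dtype)
        out.append(FusedSlice(data=data, z=z))
    return out


def downsample_once(volume_group: np.ndarray) -> np.ndarray:
    """Halve a 3D block: each output voxel is the mean of its 2x2x2 source
    block (partial blocks at odd edges average the available voxels).

    Returns float64; rounding to the output dtype happens on write.
    """
    out = np.asarray(volume_group, dtype=np.float64)
    for axis in range(3):
        n = out.shape[axis]
        idx = np.arange(0, n, 2)
        sums = np.add.reduceat(out, idx, axis=axis)
        counts = np.diff(np.append(idx, n)).astype(np.float64)
        shape = [1, 1, 1]
        shape[axis] = len(idx)
        out = sums / counts.reshape(shape)
    return out


def _level_dims(dims: tuple[int, int, int], level: int) -> tuple[int, int, int]:
    v, h, d = dims
    for _ in range(level):
        v, h, d = -(-v // 2), -(-h // 2), -(-d // 2)
    return v, h, d


def write_pyramid(
    state: StitchState,
    config: MergeConfig,
    out_path: str | Path,
    row_range: tuple[int, int] | None = None,
    col_range: tuple[int, int] | None = None,
    slice_range: tuple[int, int] | None = None,
    overwrite: bool = False,
    counters: Counters | None = None,
) -> Path:
    """Fuse the whole (or selected) volume and write every pyramid level.

    Levels live in directories ``RES(VxHxD)`` named by their dimensions;
    inside, slices are written in the same two-level stack dialect the
    importer reads (a single stack covering the footprint, or a mosaic of
    ``multistack_dims`` sub-stacks).  The volume is processed in groups of
    2**n_levels slices and each fused voxel is written exactly once.
    """
    state.require_stage("placed")
    counters = counters if counters is not None else Counters()
    out = Path(out_path)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise StitchError(f"output path {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    vol = state.volume
    rows = (0, vol.n_rows) if row_range is None else row_range
    cols = (0, vol.n_cols) if col_range is None else col_range
    (_, _), (_, _), (d_lo, d_hi) = _footprint(
        state, range(*rows), range(*cols)
    )
    if slice_range is not None:
        d_lo = max(d_lo, slice_range[0])
        d_hi = min(d_hi, slice_range[1])
    if d_hi <= d_lo:
        raise ValidationError("empty slice selection")
    (v_lo, v_hi), (h_lo, h_hi), _ = _footprint(state, range(*rows), range(*cols))
    dims0 = (v_hi - v_lo, h_hi - h_lo, d_hi - d_lo)

    level_dirs = []
    for k in range(config.n_levels + 1):
        dv, dh, dd = _level_dims(dims0, k)
        ldir = out / f"RES({dv}x{dh}x{dd})"
        ldir.mkdir(exist_ok=True)
        level_dirs.append(ldir)

    group = config.group_size
    for g0 in range(d_lo, d_hi, group):
        g1 = min(g0 + group, d_hi)
        fused = fuse_slice_group(
            state, range(g0, g1), config, rows, cols, counters
        )
        block = np.stack([fs.data for fs in fused], axis=-1)
        info = np.iinfo(np.dtype(vol.dtype))
        for k in range(config.n_levels + 1):
            if k > 0:
                block = np.clip(
                    np.rint(downsample_once(block)), info.min, info.max
                ).astype(vol.dtype)
            z_base = (g0 - d_lo) >> k
            _write_level_slices(
                block, level_dirs[k], z_base, vol, config, level=k
            )
    return out


def _write_level_slices(
    block: np.ndarray,
    level_dir: Path,
    z_base: int,
    vol,
    config: MergeConfig,
    level: int,
) -> None:
    fv, fh, fd = block.shape
    scale = 2**level
    if config.output_layout == "multi_stack":
        sv, sh = config.multistack_dims
    else:
        sv, sh = fv, fh
    for z in range(fd):
        plane = block[:, :, z]
        d_t = int(round((z_base + z) * vol.voxel_size[2] * scale * 10))
        for ov in range(0, fv, sv):
            v_t = int(round(ov * vol.voxel_size[0] * scale * 10))
            for oh in range(0, fh, sh):
                h_t = int(round(oh * vol.voxel_size[1] * scale * 10))
                sdir = level_dir / f"{v_t:06d}" / f"{v_t:06d}_{h_t:06d}"
                sdir.mkdir(parents=True, exist_ok=True)
                tifffile.imwrite(
                    sdir / f"{v_t:06d}_{h_t:06d}_{d_t:06d}.tif",
                    plane[ov : ov + sv, oh : oh + sh],
                )
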