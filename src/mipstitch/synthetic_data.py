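"""Synthetic phantoms and jittered tile hierarchies with known ground truth.

Real tiled acquisitions come from a motorized stage whose recorded
coordinates are only approximately right, and whose tiles share a known
overlap band.  This module emulates that geometry: a phantom volume with
filamentous and blob-like fluorescent structure is cut into an R x C grid of
overlapping tiles, each tile cropped at its nominal grid position plus an
integer jitter (the stage error), with independent additive Gaussian noise
per tile so that the two copies of an overlap region differ, as in a real
acquisition.  The injected jitters are returned as ground truth, which is
what the alignment stage must recover.

Integer jitter is drawn uniformly on [-jitter_max, +jitter_max] per
direction per tile, with the (0, 0) anchor tile fixed at zero; this makes a
"+-1 voxel" acceptance band crisp.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .volume_model import GridError, TiledVolume, import_volume

__all__ = [
    "GroundTruth",
    "make_phantom",
    "tile_phantom",
    "make_benchmark_hierarchy",
    "load_ground_truth",
    "BENCHMARK",
]

#: Standard synthetic benchmark conditions (grid, tile size, overlap,
#: stage-error bound, per-tile noise).  Structures reach ~150-255 grey
#: levels over a background of 8, so sigma 12 keeps the SNR well above 5.
BENCHMARK = {
    "n_rows": 3,
    "n_cols": 3,
    "tile_shape": (128, 128, 150),
    "overlap_vh": (24, 24),
    "jitter_max": 5,
    "noise_sigma": 12.0,
    "content_density": 1.0,
    "empty_fraction": 0.0,
}

_BACKGROUND = 8


@dataclass
class GroundTruth:
    """Injected per-tile truth: the oracle the pipeline is judged against."""

    true_position: dict[tuple[int, int], tuple[int, int, int]]
    jitter: dict[tuple[int, int], tuple[int, int, int]]
    seed: int

    def true_pair_displacement(
        self, key: tuple[tuple[int, int], tuple[int, int]]
    ) -> tuple[int, int, int]:
        """True correction relative to nominal for an adjacent pair (b minus a)."""
        ja, jb = self.jitter[key[0]], self.jitter[key[1]]
        return (jb[0] - ja[0], jb[1] - ja[1], jb[2] - ja[2])

    def save_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["seed", self.seed])
            writer.writerow(
                ["row", "col", "true_v", "true_h", "true_d", "jit_v", "jit_h", "jit_d"]
            )
            for key in sorted(self.true_position):
                writer.writerow(list(key) + list(self.true_position[key]) + list(self.jitter[key]))


def load_ground_truth(path: str | Path) -> GroundTruth:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    seed = int(rows[0][1])
    true_position, jitter = {}, {}
    for rec in rows[2:]:
        r, c, tv, th, td, jv, jh, jd = (int(x) for x in rec)
        true_position[(r, c)] = (tv, th, td)
        jitter[(r, c)] = (jv, jh, jd)
    return GroundTruth(true_position=true_position, jitter=jitter, seed=seed)


def make_phantom(
    shape_vhd: tuple[int, int, int],
    content_density: float = 1.0,
    empty_fraction: float = 0.0,
    seed: int = 0,
    dtype=np.uint8,
) -> np.ndarray:
    """Deterministic phantom: curvilinear filaments and Gaussian blobs on a
    dark background, with an optional contiguous background-only slab.

    ``content_density`` scales the number of structures (1.0 gives texture
    dense enough that any plausible overlap band contains signal);
    ``empty_fraction`` reserves a trailing slab along V that stays at the
    background level, emulating information-free regions of a labeled
    specimen.
    """
    shape = tuple(int(s) for s in shape_vhd)
    if any(s <= 0 for s in shape):
        raise ValueError(f"phantom shape must be positive, got {shape}")
    if not (0.0 <= empty_fraction < 1.0):
        raise ValueError(f"empty_fraction must be in [0, 1), got {empty_fraction}")
    rng = np.random.default_rng(seed)
    structures = np.zeros(shape, dtype=np.float64)
    v_content = shape[0] - int(round(empty_fraction * shape[0]))
    v_content = max(1, v_content)
    n_vox = shape[0] * shape[1] * shape[2]

    if content_density > 0:
        n_filaments = max(1, int(round(content_density * n_vox / 3e5)))
        n_blobs = max(1, int(round(content_density * n_vox / 1e5)))
        for _ in range(n_filaments):
            pos = rng.uniform([0, 0, 0], [v_content, shape[1], shape[2]])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            amplitude = rng.uniform(150, 255)
            n_steps = int(1.5 * max(shape))
            for _ in range(n_steps):
                iv, ih, id_ = (int(x) for x in pos)
                if 0 <= iv < shape[0] and 0 <= ih < shape[1] and 0 <= id_ < shape[2]:
                    structures[iv, ih, id_] = max(structures[iv, ih, id_], amplitude)
                direction += rng.normal(scale=0.35, size=3)
                direction /= np.linalg.norm(direction)
                pos += direction
        structures = gaussian_filter(structures, sigma=0.7)
        for _ in range(n_blobs):
            center = rng.uniform([0, 0, 0], [v_content, shape[1], shape[2]])
            sigma = rng.uniform(1.0, 2.5)
            amplitude = rng.uniform(100, 255)
            half = int(np.ceil(3 * sigma))
            lo = np.maximum(np.floor(center).astype(int) - half, 0)
            hi = np.minimum(np.floor(center).astype(int) + half + 1, shape)
            grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            bump = amplitude * np.exp(-dist2 / (2 * sigma**2))
            region = structures[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            np.maximum(region, bump, out=region)

    structures[v_content:, :, :] = 0.0  # keep the empty slab background-only
    vol = _BACKGROUND + structures
    info = np.iinfo(dtype)
    return np.clip(np.rint(vol), info.min, info.max).astype(dtype)


def _as_pair(overlap_vh) -> tuple[int, int]:
    if np.isscalar(overlap_vh):
        return (int(overlap_vh), int(overlap_vh))
    ov = tuple(int(x) for x in overlap_vh)
    return (ov[0], ov[1])


def tile_phantom(
    phantom: np.ndarray,
    n_rows: int,
    n_cols: int,
    tile_shape: tuple[int, int, int],
    overlap_vh,
    jitter_max: int,
    noise_sigma: float,
    seed: int,
    out_path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[TiledVolume, GroundTruth]:
    """Cut ``phantom`` into a jittered, noisy tile hierarchy on disk.

    Nominal coordinates encode the ideal jitter-free grid; each tile's
    actual crop is taken at nominal + jitter (plus a ``jitter_max`` safety
    margin inside the phantom so crops never leave it).  Noise is drawn
    independently per tile.  Writes the same directory/TIFF dialect that
    :func:`mipstitch.volume_model.import_volume` reads, plus a
    ``ground_truth.csv`` sidecar inside the root.
    """
    tile_v, tile_h, tile_d = (int(s) for s in tile_shape)
    ov_v, ov_h = _as_pair(overlap_vh)
    jitter_max = int(jitter_max)
    if min(ov_v, ov_h) < 2 * jitter_max + 1:
        raise GridError(
            f"overlap {(ov_v, ov_h)} must be >= 2*jitter_max+1 = {2 * jitter_max + 1}"
        )
    step_v, step_h = tile_v - ov_v, tile_h - ov_h
    need = (
        (n_rows - 1) * step_v + tile_v + 2 * jitter_max,
        (n_cols - 1) * step_h + tile_h + 2 * jitter_max,
        tile_d + 2 * jitter_max,
    )
    if any(p < n for p, n in zip(phantom.shape, need)):
        raise GridError(
            f"phantom shape {phantom.shape} too small for grid needing {need}"
        )

    rng = np.random.default_rng(seed)
    jitters = rng.integers(-jitter_max, jitter_max + 1, size=(n_rows, n_cols, 3))
    jitters[0, 0] = 0

    root = Path(out_path)
    root.mkdir(parents=True, exist_ok=True)
    info = np.iinfo(phantom.dtype)
    true_position, jitter_map = {}, {}
    for r in range(n_rows):
        for c in range(n_cols):
            nominal = np.array([r * step_v, c * step_h, 0])
            jit = jitters[r, c]
            origin = nominal + jit + jitter_max  # margin keeps crops inside
            crop = phantom[
                origin[0] : origin[0] + tile_v,
                origin[1] : origin[1] + tile_h,
                origin[2] : origin[2] + tile_d,
            ].astype(np.float64)
            if noise_sigma > 0:
                crop = crop + rng.normal(0.0, noise_sigma, size=crop.shape)
            tile = np.clip(np.rint(crop), info.min, info.max).astype(phantom.dtype)

            v_t = int(round(nominal[0] * voxel_size[0] * 10))
            h_t = int(round(nominal[1] * voxel_size[1] * 10))
            tdir = root / f"{v_t:06d}" / f"{v_t:06d}_{h_t:06d}"
            tdir.mkdir(parents=True, exist_ok=True)
            for z in range(tile_d):
                d_t = int(round(z * voxel_size[2] * 10))
                tifffile.imwrite(
                    tdir / f"{v_t:06d}_{h_t:06d}_{d_t:06d}.tif", tile[:, :, z]
                )
            true_position[(r, c)] = tuple(int(x) for x in (nominal + jit))
            jitter_map[(r, c)] = tuple(int(x) for x in jit)

    truth = GroundTruth(true_position=true_position, jitter=jitter_map, seed=seed)
    truth.save_csv(root / "ground_truth.csv")
    volume = import_volume(root, voxel_size)
    return volume, truth


def make_benchmark_hierarchy(
    out_path: str | Path, seed: int, **overrides
) -> tuple[TiledVolume, GroundTruth, np.ndarray]:
    """Generate the standard synthetic benchmark (see :data:`BENCHMARK`).

    Returns the imported volume, the ground truth, and the phantom array
    (handy as an untiling oracle for end-to-end fusion checks).
    """
    params = dict(BENCHMARK)
    params.update(overrides)
    tile_v, tile_h, tile_d = params["tile_shape"]
    ov_v, ov_h = _as_pair(params["overlap_vh"])
    jmax = params["jitter_max"]
    shape = (
        (params["n_rows"] - 1) * (tile_v - ov_v) + tile_v + 2 * jmax,
        (params["n_cols"] - 1) * (tile_h - ov_h) + tile_h + 2 * jmax,
        tile_d + 2 * jmax,
    )
    phantom = make_phantom(
        shape,
        content_density=params["content_density"],
        empty_fraction=params["empty_fraction"],
        seed=seed,
    )
    volume, truth = tile_phantom(
        phantom,
        params["n_rows"],
        params["n_cols"],
        params["tile_shape"],
        params["overlap_vh"],
        params["jitter_max"],
        params["noise_sigma"],
        seed=seed + 1,
        out_path=out_path,
    )
    return volume, truth, phantom
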