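"""Pairwise tile alignment by the multi-MIP-NCC method.

For each pair of adjacent tiles, the nominally overlapping region (known
from stage coordinates) is condensed into three 2D maximum-intensity
projections (MIPs), one along each of V, H and D.  A normalized
cross-correlation (NCC) map over a (2*delta+1)^2 search window is computed
for each pair of homologous MIPs; each map's peak resolves a 2D shift, so
every direction receives exactly two candidate displacements (6 in total)
and the more reliable one is kept.  Reliability combines the NCC peak value
(higher = better) with the peak width (narrower = better) into a score in
[0, 1].

Tiles are split along D into substacks of ``n_slices`` slices and each
substack pair is aligned separately, producing a redundant set of estimates
per tile pair; the projection step later collapses the redundancy.  The
whole volume is processed one layer of substacks at a time, traversing the
smaller grid dimension innermost, so that at most min{n_rows, n_cols} + 1
substacks are ever resident and every slice is read exactly once.

Sign convention: a candidate ``offset`` is the correction to apply to the
*second* tile of the pair, i.e. true_b - true_a = nominal_b - nominal_a +
offset per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instrumentation import Counters
from .volume_model import (
    DIRECTIONS,
    PairDisplacement,
    PairKey,
    StitchError,
    StitchState,
    SubstackRef,
    Tile,
    TiledVolume,
    ValidationError,
    load_substack,
    pair_axis,
)

__all__ = [
    "AlignConfig",
    "NccMap",
    "CandidateDisplacement",
    "PairDisplacement",
    "SubstackAlignment",
    "compute_overlap_rois",
    "mip",
    "ncc_map",
    "peak_and_width",
    "reliability",
    "align_substack_pair",
    "align_volume",
]

_AXIS_INDEX = {"V": 0, "H": 1, "D": 2}

#: MIP axis -> the two directions its NCC map resolves (remaining axes in
#: V, H, D order).  Processed in this order; ties in reliability keep the
#: earlier candidate.
MIP_MAPS: tuple[tuple[str, tuple[str, str]], ...] = (
    ("D", ("V", "H")),
    ("V", ("H", "D")),
    ("H", ("V", "D")),
)


@dataclass(frozen=True)
class AlignConfig:
    """Parameters of the pairwise alignment step.

    ``n_slices`` is the substack depth (typical values 100-200);
    ``delta_search`` the search half-width in voxels (the NCC window has
    side 2*delta_search + 1 and every overlap extent must exceed twice it);
    ``width_fraction`` the relative height at which the NCC peak width is
    measured.
    """

    n_slices: int = 100
    delta_search: int = 10
    width_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValidationError("n_slices must be >= 1")
        if self.delta_search < 1:
            raise ValidationError("delta_search must be >= 1")
        if not (0.0 < self.width_fraction < 1.0):
            raise ValidationError("width_fraction must be in (0, 1)")


@dataclass
class NccMap:
    """A (2*delta+1)^2 NCC surface with its peak statistics.

    ``values[u + delta, v + delta]`` is the zero-mean NCC of ``img_a`` and
    ``img_b`` sampled at ``x + (u, v)``, computed over their intersection
    after the shift.  ``axes`` names the two directions the map resolves.
    ``degenerate`` flags an all-constant input (map of zeros, not an error).
    """

    values: np.ndarray
    axes: tuple[str, str]
    peak_shift: tuple[int, int]
    peak_value: float
    widths: tuple[int, int]
    degenerate: bool = False

    @property
    def side(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CandidateDisplacement:
    direction: str
    offset: int
    peak_value: float
    width: int
    reliability: float
    mip_axis: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.reliability <= 1.0):
            raise ValidationError(f"reliability {self.reliability} outside [0, 1]")


@dataclass
class SubstackAlignment:
    """All six candidates of one substack pair plus the per-direction best."""

    candidates: list[CandidateDisplacement]
    best: dict[str, CandidateDisplacement]


Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


def compute_overlap_rois(
    tile_a: Tile,
    tile_b: Tile,
    adjacency_direction: str,
    tile_shape: tuple[int, int, int],
    delta_search: int = 0,
) -> tuple[Box, Box]:
    """Half-open 3D boxes (local to each tile) of the nominal overlap region.

    Boxes are the intersection of the two tiles' nominal extents, expanded
    by ``delta_search`` along the non-adjacency directions where both tiles
    have data (which clips the expansion back to the intersection, so the
    search window always compares valid voxels); both boxes have equal
    shapes.
    """
    if adjacency_direction not in _AXIS_INDEX:
        raise ValidationError(f"unknown adjacency direction {adjacency_direction!r}")
    nom_a = (tile_a.nominal_v, tile_a.nominal_h, tile_a.nominal_d)
    nom_b = (tile_b.nominal_v, tile_b.nominal_h, tile_b.nominal_d)
    roi_a: list[tuple[int, int]] = []
    roi_b: list[tuple[int, int]] = []
    for axis in range(3):
        lo = max(nom_a[axis], nom_b[axis])
        hi = min(nom_a[axis] + tile_shape[axis], nom_b[axis] + tile_shape[axis])
        if axis != _AXIS_INDEX[adjacency_direction]:
            lo_x = max(lo - delta_search, nom_a[axis], nom_b[axis])
            hi_x = min(
                hi + delta_search,
                nom_a[axis] + tile_shape[axis],
                nom_b[axis] + tile_shape[axis],
            )
            lo, hi = lo_x, hi_x
        if hi - lo < 1:
            raise StitchError(
                f"no overlap along {DIRECTIONS[axis]} between tiles "
                f"({tile_a.row}, {tile_a.col}) and ({tile_b.row}, {tile_b.col})"
            )
        roi_a.append((lo - nom_a[axis], hi - nom_a[axis]))
        roi_b.append((lo - nom_b[axis], hi - nom_b[axis]))
    return tuple(roi_a), tuple(roi_b)  # type: ignore[return-value]


def mip(substack: np.ndarray, axis: str | int) -> np.ndarray:
    """Maximum intensity projection along one axis (V=0, H=1, D=2).

    Output axes keep the remaining axes in V, H, D order.
    """
    if isinstance(axis, str):
        axis = _AXIS_INDEX[axis]
    arr = np.asarray(substack)
    if arr.size == 0:
        raise ValidationError("cannot project an empty array")
    return arr.max(axis=axis)


def peak_and_width(
    values: np.ndarray, width_fraction: float = 0.75
) -> tuple[tuple[int, int], float, tuple[int, int]]:
    """Locate the map peak and measure its widths along both map axes.

    Ties at the maximum are broken toward the smallest Euclidean shift from
    the map centre, then lexicographically.  The width along an axis is the
    number of contiguous cells through the peak whose value is at least
    ``width_fraction`` times the peak value (the peak cell always counts).
    """
    values = np.asarray(values, dtype=np.float64)
    delta = (values.shape[0] - 1) // 2
    peak_value = float(values.max())
    ties = np.argwhere(values == peak_value)
    shifts = ties - delta
    order = np.lexsort((shifts[:, 1], shifts[:, 0], (shifts**2).sum(axis=1)))
    pi, pj = ties[order[0]]
    peak_shift = (int(pi - delta), int(pj - delta))

    thr = width_fraction * peak_value
    widths = []
    for axis, idx in ((0, pi), (1, pj)):
        line = values[:, pj] if axis == 0 else values[pi, :]
        w = 1
        k = idx - 1
        while k >= 0 and line[k] >= thr:
            w += 1
            k -= 1
        k = idx + 1
        while k < line.size and line[k] >= thr:
            w += 1
            k += 1
        widths.append(w)
    return peak_shift, peak_value, (widths[0], widths[1])


def ncc_map(
    img_a: np.ndarray,
    img_b: np.ndarray,
    delta_search: int,
    width_fraction: float = 0.75,
    axes: tuple[str, str] = ("V", "H"),
) -> NccMap:
    """Zero-mean NCC of two equally shaped images over all shifts in
    [-delta, delta]^2, each score computed on the post-shift intersection.

    Shifts where either operand has zero variance score 0, so maps stay
    defined on empty regions; two entirely constant images yield a flagged
    all-zero map rather than an error.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"image shapes differ: {a.shape} vs {b.shape}")
    n0, n1 = a.shape
    d = int(delta_search)
    if n0 <= 2 * d or n1 <= 2 * d:
        raise ValidationError(
            f"image shape {a.shape} must be strictly larger than 2*delta = {2 * d} "
            "in both axes"
        )
    side = 2 * d + 1
    values = np.zeros((side, side), dtype=np.float64)
    degenerate = (a.max() == a.min()) and (b.max() == b.min())
    if not degenerate:
        for u in range(-d, d + 1):
            a0, a1 = max(0, -u), n0 - max(0, u)
            b0, b1 = max(0, u), n0 - max(0, -u)
            for v in range(-d, d + 1):
                asub = a[a0:a1, max(0, -v) : n1 - max(0, v)]
                bsub = b[b0:b1, max(0, v) : n1 - max(0, -v)]
                am = asub - asub.mean()
                bm = bsub - bsub.mean()
                denom = np.sqrt((am * am).sum() * (bm * bm).sum())
                if denom > 0:
                    values[u + d, v + d] = (am * bm).sum() / denom
        np.clip(values, -1.0, 1.0, out=values)
    peak_shift, peak_value, widths = peak_and_width(values, width_fraction)
    return NccMap(
        values=values,
        axes=axes,
        peak_shift=peak_shift,
        peak_value=peak_value,
        widths=widths,
        degenerate=degenerate,
    )


def reliability(peak_value: float, width: int, map_side: int) -> float:
    """Combine peak value and peak width into a reliability score in [0, 1].

    r = max(0, peak) * (side - width) / (side - 1): equal to the peak value
    for a one-cell-wide peak, falling linearly to 0 as the peak widens to
    the full map side, and 0 for non-positive peaks.  Monotone
    non-decreasing in the peak value and non-increasing in the width.
    """
    if not (1 <= width <= map_side):
        raise ValidationError(f"width {width} outside [1, {map_side}]")
    if map_side <= 1:
        return float(np.clip(max(0.0, peak_value), 0.0, 1.0))
    r = max(0.0, float(peak_value)) * (map_side - width) / (map_side - 1)
    return float(np.clip(r, 0.0, 1.0))


def align_substack_pair(
    sub_a: np.ndarray,
    sub_b: np.ndarray,
    adjacency_direction: str,
    config: AlignConfig,
) -> SubstackAlignment:
    """Align one pair of homologous overlap substacks.

    Three MIPs per substack, three NCC maps, two candidates per direction
    (six in total); the more reliable candidate per direction is kept.  An
    all-constant overlap yields zero offsets with reliability 0.
    """
    if sub_a.shape != sub_b.shape:
        raise ValidationError(
            f"substack shapes differ: {sub_a.shape} vs {sub_b.shape}"
        )
    side = 2 * config.delta_search + 1
    candidates: list[CandidateDisplacement] = []
    for mip_axis, axes in MIP_MAPS:
        nm = ncc_map(
            mip(sub_a, mip_axis),
            mip(sub_b, mip_axis),
            config.delta_search,
            config.width_fraction,
            axes=axes,
        )
        for i, direction in enumerate(axes):
            if nm.degenerate:
                cand = CandidateDisplacement(
                    direction=direction, offset=0, peak_value=0.0,
                    width=nm.widths[i], reliability=0.0, mip_axis=mip_axis,
                )
            else:
                cand = CandidateDisplacement(
                    direction=direction,
                    offset=-int(nm.peak_shift[i]),
                    peak_value=nm.peak_value,
                    width=nm.widths[i],
                    reliability=reliability(nm.peak_value, nm.widths[i], side),
                    mip_axis=mip_axis,
                )
            candidates.append(cand)
    best: dict[str, CandidateDisplacement] = {}
    for cand in candidates:
        cur = best.get(cand.direction)
        if cur is None or cand.reliability > cur.reliability:
            best[cand.direction] = cand
    return SubstackAlignment(candidates=candidates, best=best)


# --------------------------------------------------------------------------
# volume-level streaming alignment
# --------------------------------------------------------------------------


def _layers(d0: int, d1: int, n_slices: int) -> list[tuple[int, int]]:
    return [(z, min(z + n_slices, d1)) for z in range(d0, d1, n_slices)]


def _normalize_range(rng, size: int, name: str) -> tuple[int, int]:
    if rng is None:
        return (0, size)
    lo, hi = int(rng[0]), int(rng[1])
    if not (0 <= lo < hi <= size):
        raise ValidationError(f"empty or out-of-bounds {name} selection [{lo}, {hi})")
    return (lo, hi)


def align_volume(
    volume: TiledVolume,
    config: AlignConfig,
    row_range: tuple[int, int] | None = None,
    col_range: tuple[int, int] | None = None,
    slice_range: tuple[int, int] | None = None,
    counters: Counters | None = None,
) -> StitchState:
    """Compute per-substack displacements for every adjacent pair in the
    (optionally restricted) grid, one layer of substacks at a time.

    The grid is traversed row-wise when n_rows >= n_cols and column-wise
    otherwise; a substack is released as soon as all pairs involving it are
    done, so at most min{n_rows, n_cols} + 1 substacks are resident and each
    slice file is read exactly once.  The optional ranges implement the
    preview feature (align only part of the grid/depth).
    """
    counters = counters if counters is not None else Counters()
    r0, r1 = _normalize_range(row_range, volume.n_rows, "row")
    c0, c1 = _normalize_range(col_range, volume.n_cols, "col")
    d0, d1 = _normalize_range(slice_range, volume.n_slices_total, "slice")
    n_rows_sel, n_cols_sel = r1 - r0, c1 - c0
    row_wise = n_rows_sel >= n_cols_sel

    if row_wise:
        order = [(r, c) for r in range(r0, r1) for c in range(c0, c1)]
    else:
        order = [(r, c) for c in range(c0, c1) for r in range(r0, r1)]

    budget = min(n_rows_sel, n_cols_sel) + 1
    results: dict[PairKey, list[PairDisplacement]] = {}
    for z0, z1 in _layers(d0, d1, config.n_slices):
        cache: dict[tuple[int, int], np.ndarray] = {}
        remaining: dict[tuple[int, int], int] = {}

        def release(key: tuple[int, int]) -> None:
            del cache[key]
            counters.substack_released()

        for (r, c) in order:
            tile = volume.tile(r, c)
            cache[(r, c)] = load_substack(
                volume, SubstackRef(tile, z0, z1), counters
            )
            counters.substack_loaded()
            if counters.resident_substacks > budget:
                raise StitchError(
                    f"memory contract violated: {counters.resident_substacks} "
                    f"resident substacks exceed budget {budget}"
                )
            remaining[(r, c)] = int(r + 1 < r1) + int(c + 1 < c1)
            for prev in ((r - 1, c), (r, c - 1)):
                if prev[0] < r0 or prev[1] < c0:
                    continue
                key: PairKey = (prev, (r, c))
                pd = _align_pair_layer(
                    volume, key, cache[prev], cache[(r, c)], z0, z1, config
                )
                results.setdefault(key, []).append(pd)
                remaining[prev] -= 1
                if remaining[prev] == 0:
                    release(prev)
            if remaining[(r, c)] == 0:
                release((r, c))
        assert not cache, "all substacks must be released at end of layer"

    return StitchState(
        stage="displacements_computed",
        volume=volume,
        pair_displacements=results,  # type: ignore[arg-type]
    )


def _align_pair_layer(
    volume: TiledVolume,
    key: PairKey,
    sub_a: np.ndarray,
    sub_b: np.ndarray,
    z0: int,
    z1: int,
    config: AlignConfig,
) -> PairDisplacement:
    axis = pair_axis(key)
    tile_a = volume.tile(*key[0])
    tile_b = volume.tile(*key[1])
    roi_a, roi_b = compute_overlap_rois(
        tile_a, tile_b, axis, volume.tile_shape, config.delta_search
    )
    # restrict the ROI's D extent to this layer, in each tile's local slices
    ga = (roi_a[2][0] + tile_a.nominal_d, roi_a[2][1] + tile_a.nominal_d)
    gb = (roi_b[2][0] + tile_b.nominal_d, roi_b[2][1] + tile_b.nominal_d)
    g_lo = max(ga[0], gb[0], z0 + tile_a.nominal_d, z0 + tile_b.nominal_d)
    g_hi = min(ga[1], gb[1], z1 + tile_a.nominal_d, z1 + tile_b.nominal_d)
    if g_hi - g_lo < 1:
        raise StitchError(f"no common slices for pair {key} in layer [{z0}, {z1})")
    a = sub_a[
        roi_a[0][0] : roi_a[0][1],
        roi_a[1][0] : roi_a[1][1],
        g_lo - tile_a.nominal_d - z0 : g_hi - tile_a.nominal_d - z0,
    ]
    b = sub_b[
        roi_b[0][0] : roi_b[0][1],
        roi_b[1][0] : roi_b[1][1],
        g_lo - tile_b.nominal_d - z0 : g_hi - tile_b.nominal_d - z0,
    ]
    aligned = align_substack_pair(a, b, axis, config)
    return PairDisplacement(
        pair=key,
        offsets=tuple(aligned.best[d].offset for d in DIRECTIONS),  # type: ignore[arg-type]
        reliabilities=tuple(aligned.best[d].reliability for d in DIRECTIONS),  # type: ignore[arg-type]
        z0=z0,
        z1=z1,
    )
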