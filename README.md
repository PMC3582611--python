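# mipstitch

Stepwise 3D stitching of tiled microscopy volumes.

Large specimens imaged by light-sheet or confocal microscopy are acquired
as a grid of overlapping 3D tiles, each a stack of 2D slices, at stage
positions that are recorded but not precise enough for direct assembly.
`mipstitch` reconstructs the whole volume from such a tile matrix under
explicit memory bounds, so that volumes far larger than RAM can be
stitched: it imports the tile hierarchy, estimates pairwise displacements,
solves a globally consistent placement, and stream-merges the tiles into a
blended, multiresolution image — with editable XML state between steps so
a user can inspect, hand-correct and resume the pipeline.

## Method

The tile matrix has axes V (vertical/rows), H (horizontal/columns) and D
(depth/slices). The pipeline is:

1. **Import** — scan the two-level directory hierarchy (first level encodes
   the V stage position, second level V_H, slice files V_H_D, in tenths of
   a micrometre) and convert nominal stage coordinates to voxels.
2. **Align** — for every pair of adjacent tiles, split the tiles along D
   into substacks of `n_slices` slices (typically 100–200). For each
   homologous substack pair, condense the nominally overlapping region into
   three maximum-intensity projections (MIPs), one along each axis, and
   compute a normalized cross-correlation (NCC) map per MIP pair over a
   (2δ+1)² search window. Each map's peak resolves two of the three
   directions, so every direction gets **two candidate displacements (six
   in total)**; each candidate carries a reliability
   r = max(0, peak) · (side − width)/(side − 1) ∈ [0, 1]
   combining the NCC peak value (higher = better) with the peak width
   (narrower = better), and the more reliable candidate per direction is
   kept. The volume is processed one layer of substacks at a time with at
   most min{N_rows, N_cols}+1 substacks resident and each slice read once.
3. **Project** — collapse the per-substack redundancy: per direction,
   keep the estimate with the highest reliability across layers.
4. **Threshold** — pairs whose aggregate reliability falls below a
   threshold (good values: 0.7–0.8) revert to stage coordinates with
   reliability 0 and are marked *nonstitchable*; a tile is nonstitchable
   iff all its incident pairs are.
5. **Place** — per direction, build the tile mesh with edge weights
   1/r (∞ when r = 0) and take its minimum spanning tree; absolute
   coordinates accumulate nominal offset + correction along the tree from
   the anchor tile (0, 0). Infinite edges enter only when connectivity
   demands and contribute the plain stage displacement.
6. **Merge** — fuse tiles stripe-by-stripe (along H within a tile row,
   then rows along V). Non-overlap pixels are copied verbatim; overlaps are
   blended with two sinusoidal weights phase-shifted by π,
   w₁ = (1 + cos πt)/2, w₂ = 1 − w₁, with t running across the overlap.
   The result is written as a multiresolution pyramid where each coarser
   voxel is the mean of a 2×2×2 block, processing the volume in groups of
   2^levels slices (32 slices for the usual 5 levels).

A synthetic-data module generates ground-truth phantoms cut into jittered,
noisy tile hierarchies, so the whole pipeline is testable without any
acquisition: the injected per-tile jitter is exactly what alignment must
recover.

## Worked example

Stitch a synthetic 2×2 volume (64×64×40 tiles, 16-voxel overlap, stage
jitter up to 3 voxels, noisy):

```python
import mipstitch as ms

volume, truth, _ = ms.make_benchmark_hierarchy(
    "work/volume", seed=11, n_rows=2, n_cols=2, tile_shape=(64, 64, 40),
    overlap_vh=(16, 16), jitter_max=3, noise_sigma=6.0, content_density=4.0,
)
state = ms.align_volume(volume, ms.AlignConfig(n_slices=20, delta_search=7))
state = ms.project_state(state)
for key, pd in sorted(state.pair_displacements.items()):
    print(key, "estimated", pd.offsets,
          "true", truth.true_pair_displacement(key),
          "reliability", tuple(round(r, 2) for r in pd.reliabilities))
state = ms.threshold_state(state, ms.ThresholdConfig(0.7))
state = ms.solve_placement(state)
ms.write_pyramid(state, ms.MergeConfig(n_levels=2), "work/pyramid")
```

prints

```
((0, 0), (0, 1)) estimated (3, -3, -2) true (3, -3, -2) reliability (0.84, 0.91, 0.84)
((0, 0), (1, 0)) estimated (-2, -2, 1) true (-2, -2, 1) reliability (0.78, 0.77, 0.65)
((0, 1), (1, 1)) estimated (-4, 3, 0) true (-4, 3, 0) reliability (0.78, 0.84, 0.85)
((1, 0), (1, 1)) estimated (1, 2, -3) true (1, 2, -3) reliability (0.7, 0.78, 0.71)
```

Every estimated (V, H, D) correction equals the injected stage jitter
difference exactly, with per-direction reliabilities of 0.65–0.91; pairs
this reliable survive the 0.7 threshold and drive the MST placement. The
pyramid directory then holds `RES(111x114x43)`, `RES(56x57x22)` and
`RES(28x29x11)` — the fused volume at full, half and quarter resolution.

The same pipeline is available from the shell, one step per invocation
with XML state in between (edit the XML between steps to override
displacements, reliabilities or stitchable flags by hand):

```sh
mipstitch import work/volume --xml-out imported.xml
mipstitch align --xml-in imported.xml --xml-out aligned.xml --subvoldim 20 --search 7
mipstitch project --xml-in aligned.xml --xml-out projected.xml
mipstitch threshold --xml-in projected.xml --xml-out thresholded.xml --threshold 0.7
mipstitch report --xml-in thresholded.xml
mipstitch place --xml-in thresholded.xml --xml-out placed.xml
mipstitch merge --xml-in placed.xml --out pyramid --resolutions 2
```

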