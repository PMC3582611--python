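# Methods

## Model and assumptions

`mipstitch` assumes an acquisition by a motorized stage: a complete
R×C matrix of identically shaped 3D tiles (no holes, no rotation, axes
parallel across tiles), each tile an ordered run of 2D grayscale slices
(8- or 16-bit TIFF) along the depth axis D. Recorded stage coordinates are
treated as a trustworthy *prior*: they are accurate enough to delimit the
overlap region of every adjacent pair and to bound the residual error by a
small search radius, but not accurate enough for direct assembly. The
pipeline therefore only ever searches for a small integer (V, H, D)
*correction* per adjacent pair, never for a global registration from
scratch. Displacement offsets are stored as these corrections relative to
the nominal stage displacement; "restoring the stage default" is storing
zero.

Alignment uses maximum-intensity projections because fluorescence
microscopy content is sparse: over a substack of 100–200 slices, a MIP
concentrates the signal without saturating. This is also why tiles are
split into substacks — a MIP over thousands of slices would accumulate too
much structure, and per-substack estimates give redundancy that the
projection step exploits (layers with little content simply lose the
per-direction reliability contest).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `n_slices` | 100 | slices | substack depth; typical range 100–200. Also the alignment memory unit: (min{R,C}+1)·n_slices slices resident. |
| `delta_search` | 10 | voxels | search half-width; the NCC window has side 2δ+1. Every overlap extent must be strictly larger than 2δ, and δ must be at least twice the worst expected per-tile stage error (the pair shift is a difference of two jitters). |
| `width_fraction` | 0.75 | — | relative height at which the NCC peak width is measured (contiguous run through the peak, per axis). |
| `reliability_threshold` | 0.7 | — | pairs below it revert to stage coordinates; good values on well-contrasted data are 0.7–0.8, lower for noisy or low-contrast data. |
| `aggregate` | `min` | — | per-pair reliability aggregation over the three directions. `min` is the conservative choice (one bad axis misplaces a tile); `mean` is available. Whether thresholding should instead act per direction is a genuinely open choice; per-pair was chosen and is switchable. |
| `n_levels` | 5 | — | pyramid halving steps; slice groups of 2^n_levels (32) bound the resident fused output. |
| `blending` | `sinusoidal` | — | `none` replaces the ramp with a hard cut at the overlap midpoint, which makes residual seams visible for inspection. |

The reliability formula r = max(0, peak) · (side − width)/(side − 1)
is the package's own combination rule; it is pinned down by the
requirements that r ∈ [0, 1], r equals the peak value for a one-cell
peak, r = 0 for non-positive peaks or a peak as wide as the whole map,
and monotonicity in both ingredients. Per direction it uses the peak
width along that direction's map axis.

## Numerical choices

- **NCC** is zero-mean and variance-normalized, computed per shift on the
  post-shift intersection of the two images. Shifts where either operand
  has zero variance score 0, so maps stay defined on information-free
  regions and such candidates get reliability 0 rather than raising.
  Two entirely constant images yield a flagged all-zero map.
- **Peak ties** break toward the smallest Euclidean shift (then
  lexicographic): with trustworthy stage coordinates, the nominal
  alignment is the best guess among equals.
- **MST** is Kruskal with edges inserted in lexicographic endpoint order,
  so equal weights resolve deterministically. Zero reliability maps to an
  IEEE infinity weight — ordered above every finite weight, never produced
  by overflow — and an infinite edge is used only when no finite edge can
  complete the spanning tree (isolated stitchable regions); such edges
  contribute the plain stage offset regardless of any stored value, which
  also makes hand-zeroing a pair's reliabilities in the XML sufficient to
  force it back to stage coordinates.
- **Placement gauge**: tree rooted at tile (0, 0), then each direction is
  translated so its minimum coordinate is 0.
- **Blending** parameter t spans the full overlap width (first to last
  overlapping pixel along the blend axis); a 1-pixel overlap uses t = 0.5.
  Fusion composes H-then-V, so a four-tile corner receives the product of
  the H and V weights. There is no blending along D: tiles contribute the
  slices they cover, elsewhere the output stays background.
- **Rounding**: fusion and downsampling accumulate in float64 and round
  half-even to the input dtype on write. Odd dimensions at any pyramid
  level truncate: the final block averages the ≤ 8 available voxels, which
  keeps the pyramid self-similar (each level's dims are the ceiling half
  of the previous).

## Synthetic data

The generator emulates the acquisition geometry, not the optics: a phantom
of curvilinear filaments and Gaussian blobs on a dark background is cut
into an R×C grid of overlapping tiles, each cropped at its nominal grid
position plus an integer jitter drawn uniformly on [−jitter_max,
+jitter_max] per direction (anchor tile (0, 0) fixed at zero — integer
truth makes a ±1-voxel acceptance band crisp), with i.i.d. Gaussian noise
added independently per tile so the two copies of an overlap differ, as in
a real acquisition. An optional contiguous background-only slab emulates
information-free regions of a selectively labeled specimen.

Not emulated: the PSF, illumination/vignetting fields, depth-dependent
attenuation, tile rotation, non-integer drift. Passing tests therefore
demonstrate the pipeline's geometric and statistical correctness under
realistic SNR and stage error, not robustness to optical artifacts; on
real data the reliability threshold is the knob that absorbs those.

The standard benchmark is a 3×3 grid of 128×128×150 uint8 tiles with
24-voxel overlap, jitter_max 5, noise sigma 12 over structures reaching
150–255 grey levels on a background of 8 (SNR well above 5), content
density 1.0. The test suite mostly works on a scaled-down 2×2 cousin
(64×64×40 tiles, overlap 16, jitter 3) with a higher structure density so
that every overlap band of the smaller volume still carries signal; the
acceptance script runs the full benchmark. Search half-widths are chosen
per geometry to satisfy 2δ < overlap and δ ≥ 2·jitter_max.

## Known limitations

- Grids with missing tiles, multi-channel data and per-axis anisotropic
  search radii are out of scope.
- Subvoxel alignment is not attempted; all corrections are integer voxels.
- The preview selectors restrict which pairs/slices are processed; states
  produced that way cover only part of the grid, and placement treats the
  missing pairs as stage-default (reliability 0) links.
- Merging blends at most the two contributors that meet along each fusion
  axis; more exotic overlap topologies (three tiles meeting along one
  axis) would fuse sequentially, not symmetrically.
- Processing is single-threaded; the layer/group streaming structure is
  what a parallel implementation would distribute, but none is provided.
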