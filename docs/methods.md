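# Methods

## Data model and conventions

Voxel grids are indexed `(z, y, x)`, 0-based; z index 0 is the first
acquired plane (top of the stack); y increases downward, matching raster
storage. Bounding boxes are half-open `[lo, hi)`. Physical voxel sizes
`(sz, sy, sx)` are in µm per voxel and are mandatory configuration for any
physical output — TIFF metadata conventions vary too much between
acquisition pipelines to guess from, so readers never infer them. The
reference scale used throughout the defaults is 0.110 µm z-steps and
0.043 µm xy pixels (high-NA Airyscan imaging of mouse cochlea).

Sessions are zip archives of a JSON manifest, the label volume as TIFF and
every analysis table as CSV: portable, versioned (`format_version`), and
inspectable with standard tools, deliberately not a language-native
serialization.

## 3D reconstruction by overlap tracking

Per-plane instance masks carry frame-local IDs with no cross-plane meaning.
Tracking links them greedily: frame-0 detections each seed a track; a later
detection is compared with each eligible track's most recent mask and joins
the one with the largest pixel overlap, provided the overlap reaches
`min_overlap` (default 1 px — "significant overlap" made explicit and
configurable). Detections with no eligible overlap seed new tracks. When
several detections claim one track, the largest overlap wins and the losers
seed new tracks — bundles are solid in z, so a losing fragment is more
plausibly a new object (or a split) than a second slice of the same one.
Eligibility is controlled by `max_gap` (default 0: previous plane only,
since bundles are z-contiguous; raise it to bridge planes a 2D segmenter
dropped). All ties are deterministic: lower track ID for a detection torn
between tracks, larger detection area then lower local ID for detections
tied on one track. Completed tracks are painted into the label volume in
creation order.

Components spanning fewer than `min_frames` planes (default 2) or
`min_voxels` voxels (default 20 at the reference scale, ≈0.004 µm³) are
then discarded; survivors keep their IDs. Both thresholds are CLI-exposed;
the defaults remove single-plane specks that no real bundle could produce.

## Height measurement

For each instance the binary z-projection (occupancy in any plane) defines
two landmarks. The tip is the projection pixel with minimal y (tie: minimal
x), with z1 the shallowest plane containing that (y, x) voxel. The base is
found by walking straight down (+y) from the projection centroid at fixed x
until the first empty pixel, stepping back one; when the centroid itself is
off-support (common for open V shapes) the x is first snapped to the
nearest support column in the centroid row and the result is flagged
(`snapped`). z2 is the deepest plane occupied by the component. Height is
the per-axis-scaled Euclidean distance between the two landmarks. Because
z1/z2 come from the 3D support rather than a projected extent, in-plane
rotation of the specimen changes the measure only through the (smaller)
in-plane component — phantom tests bound the change at 15° rotation below
5%.

The walk operates on the projection (not a single plane): the projection is
the densest support available and the only one guaranteed to connect tip
and base for tilted bundles.

## Orientation

The projection is treated as a V: a peak (centre of the topmost pixel run —
using the run centre rather than a corner keeps a perfectly symmetric V's
axis at exactly 90°) and one anchor per side of the centroid column.
`height_only` takes each side's lowest pixel (tie: farthest from the
centroid column); it is exact on clean V shapes but fooled by J-shaped
bundles whose lowest pixel is not the wing end. `height_distance` considers
every pixel within `tolerance_px` (default 2) of the side's lowest y and
takes the one farthest from the peak, accommodating curved wings. Three
angles are derived by `atan2` in image coordinates and mapped to [0, 180):
the baseline (left→right), the axis (baseline midpoint→peak; 90° for an
upright bundle — this is the headline `orientation_deg` column, since
bundle-orientation distributions center near 90° after alignment), and the
apex opening angle. A side with no pixels falls back to `height_distance`
and flags the result degenerate.

## Depth-matched intensity

Segmentation depth dᵢ varies with signal strength, so three totals are
offered per bundle from the per-layer masked sums Sᵢ(z): (1) all occupied
layers; (2) the first n layers from the bundle's shallowest plane, with
n = min dᵢ over the comparison set, so every bundle contributes equally —
"first" meaning tip-side, the deterministic anatomical choice (a
brightest-n variant is available behind a flag); (3) the all-layer total
plus (n_max − dᵢ) copies of the bundle's weakest layer, n_max = max dᵢ.
For non-negative intensities mode 2 ≤ mode 1 ≤ mode 3, with equality when
depths match. Optional background subtraction removes, per plane, the mean
intensity outside every mask times the bundle's voxel count in that plane,
clamped at zero — the simplest estimator consistent with treating ambient
signal as spatially uniform per plane. Mean intensity divides the all-layer
total by the bundle's voxel count. Group exports produce a mean and a total
CSV (and histogram) for each of IHC, pooled OHC, OHC1, OHC2, OHC3 — ten
CSVs per stack.

## Row identity

After planar-cell-polarity alignment the rows run horizontally with IHC
bottom-most, so row identity is recoverable from base-point y alone:
cluster into k = 4 groups (KMeans with 10 seeded restarts, or a Gaussian
mixture with per-component variances for tissues where row spread differs)
and order cluster means by descending y → IHC, OHC1, OHC2, OHC3. The
y-only feature follows from the row geometry; a 2D (x, y) option exists
behind a flag. Tied cluster means indicate degenerate clustering and raise
rather than silently mislabel. Both backends are deterministic given a
seed. Clustering fails on curved or overlapping rows — an `external`
path accepts per-bundle labels from any stronger classifier.

## Frame-level logic

Zone selection: per-frame classifiers emit PCZ/CCZ/NSZ scores; argmax
labels are summarized by the longest contiguous CCZ run (classifiers may
emit stray CCZ frames; the longest run is the conservative reading) and by
the *switches* count — the number of transitions that either decrease or
repeat an already-used forward step. A clean monotone PCZ→CCZ→NSZ profile
scores exactly 0; any fluctuation scores positive.

Rotation correction: per-frame scores over 72 classes (class c ↔ c·5°) are
averaged over frames, the argmax (lowest class on ties) gives the
predicted orientation and the correction (360° − predicted) mod 360. The
corrected frame is cropped to the largest axis-aligned rectangle inscribed
in the rotated footprint (closed form; 256² at 45° → 181², i.e.
⌊256/√2⌋). Rotation resamples onto an odd-sized canvas centred on an exact
pixel; quarter-turns use lossless `rot90`; a marker plane resampled
identically guards the sub-pixel tangency of the inscribed rectangle, so no
padding value ever survives into the crop. Nearest-neighbour resampling is
the default (exact for label images); bilinear is available for intensity
frames.

Tonotopic voting: the stack-level BASE/MIDDLE/APEX call is the majority
over a 13-frame window starting at the median frame m = ⌊(F−1)/2⌋, clipped
at the stack end; ties go to the highest summed score in the window when
scores are available, else the lowest class index.

Confusion-matrix summaries report per-class one-vs-rest precision, recall,
specificity and F1 (macro-averaged; zero-denominator classes are reported
as undefined, never as 0) with accuracy as the diagonal fraction, so
accuracy + error_rate = 1.

## Detection evaluation

Ground-truth and predicted instances are matched by volumetric IoU:
candidate pairs in descending IoU, each side consumed once (a ground-truth
bundle split across two predictions keeps the larger-overlap prediction;
the other becomes a false positive). Matched pairs at or above the
threshold are TP; matched-below-threshold pairs count as both FN and FP,
preserving TP+FN = #gt and TP+FP = #pred at all 19 thresholds
(0.10…1.00 in 0.05 steps). True negatives are not counted — background
dominates a voxel grid and would swamp the metric — so accuracy is
TP/(TP+FP+FN), tied to F1 by the exact identity acc = F1/(2−F1). Greedy
matching can differ from the optimal (max total IoU) assignment when
predictions are contested; the test suite documents a constructed
divergence case, and on realistic jittered predictions the two agree.

Agreement statistics (Pearson r, paired t with df = n−1, Wilcoxon
signed-rank dropping zero differences with the exact distribution for
small tie-free samples, Mann–Whitney U) and descriptives run on any paired
measurement columns. The standard deviation is population-normalized
(divisor n) by default — the convention the packaged benchmark table's
published statistics follow — with a flag for the n−1 estimator.

## Texture

Per-bundle crops are bounding boxes of the max-intensity projection masked
to the bundle's projected support, off-support pixels set to the plane
background mean so neighbouring bundles cannot leak into the features.
GLCM features use a symmetric, normalized co-occurrence matrix (default
256 levels after min-max rescaling — offset-invariant by construction —
distance 1, angles 0/45/90/135° averaged) with contrast Σp(i−j)², energy
Σp² (angular second moment), homogeneity Σp/(1+|i−j|) and marginal-moment
correlation; a constant crop flags correlation undefined rather than 0.
LBP uses the uniform P=8, R=1 mapping → 10 bins (codes 0–8 plus
non-uniform), histogrammed over the crop interior only (border pixels
would sample outside the crop) and normalized. Group comparison is a
two-sided Mann–Whitney U per feature, exact for small tie-free samples,
with group medians reported.

## The phantom generator

Phantoms emulate an en-face, PCP-aligned confocal stack: four horizontal
rows (IHC bottom-most at the largest y, then OHC1–3 upward), each bundle a
V of two wings meeting at a peak, extruded over a contiguous z-range.
Strokes are painted by exact point-to-segment distance thresholding at
pixel centres — an isotropic stroke at any wing angle, equivalent to
supersampled rasterization but exact. The optional global rotation is
applied last, to the wing geometry about the frame centre (same content
convention as `scipy.ndimage.rotate`), so every angle rasterizes without
grid resampling and the truth angles are exact: baseline (−θ) mod 180,
axis (90° − θ) mod 180. Intensity is amplitude on strokes plus background
plus Gaussian noise, added after painting so the label volume is
noise-free. Out-of-bounds bundles raise an error listing the offending IDs
rather than clipping silently.

Default conditions: 30-plane 384×384 stacks at (0.110, 0.043, 0.043) µm
voxels; wings 60 px (~2.6 µm) at ±40° from vertical, 5 px strokes, 24
z-layers (~2.5 µm), four rows of four bundles with ±2 px positional
jitter, amplitude 200 over background 20 with noise SD 10. These put
bundle widths, depths and heights (~2.9 µm) in the anatomically realistic
range for mid-cochlear mouse bundles at this pixel size; realistic bundle
scale matters because landmark and anchor errors are quantized at ±1–2 px,
and only at realistic size does that correspond to the sub-3° angular and
sub-voxel-diagonal height accuracy the real measurement regime has.

Ground-truth tip/base landmarks are computed inside the generator by an
independent implementation of the documented landmark rules operating on
the rasterized truth volume, so the morphometry route is cross-checked
rather than self-confirmed. `degrade_to_frame_masks` turns the truth
volume into segmenter-like per-frame masks — per-plane connected
components under random frame-local IDs, with seeded per-frame dropout and
minor-axis splits as stress modes.

What phantoms do *not* emulate: PSF blur and anisotropic optical response,
cuticular-plate signal, touching/overlapping bundles within a row, curved
or converging rows (apex-like geometry), intra-bundle intensity dropout,
and depth-dependent attenuation. Passing tests therefore demonstrate the
correctness of the reconstruction, measurement and evaluation logic under
known geometry — not segmentation robustness on difficult tissue, which is
the upstream 2D segmenter's burden.

## Numerical choices and degenerate inputs

Single-voxel bundles get defined degenerate measurements (perimeter 4·sx,
eccentricity 0, height 0). All-zero label volumes produce empty tables,
not errors. Paired t on bit-identical columns returns t = 0, p = 1 (the
no-difference reading; the underlying statistic is 0/0). Zero-variance
Pearson inputs are flagged undefined. Max normalization refuses all-zero
groups. The Mann–Whitney U on an all-identical pooled sample reports p = 1
with a tie note. Every stochastic component (phantom noise and jitter,
degradation, clustering initialization) is driven by an explicit seed, and
identical seeds reproduce byte-identical CSVs through the batch pipeline.

## Problem sizes

The test suite runs phantoms between 16×160×160 (unit tests) and the
default 30×384×384 conditions (height recovery over 100 seeds, rotation
invariance over 3 seeds, orientation recovery over 6 rotation/seed
combinations); exhaustive-rule oracles run on ≤3-frame, ≤4-object series
and ≤5-instance toy volumes where enumeration is cheap. These sizes keep
the full suite under a minute of CPU while exercising the same geometry
regime as the defaults.

## Known limitations

- The base-landmark walk lands partway down a wing for thin-stroke open V
  shapes (the projection gap between wings stops it); heights are
  landmark-consistent (truth uses the same documented rule) but the base
  point is not the anatomical bundle bottom for such shapes.
- `height_only` orientation misreads J-shaped bundles (lowest ≠ most
  remote); use `height_distance` there.
- Greedy IoU matching is not the optimal assignment under contested
  predictions (documented divergence case in the tests).
- Row clustering assumes straight, separated rows; curved apical rows need
  external labels.
- The tracker links by overlap only; two bundles stacked exactly atop one
  another in z with overlapping supports would merge.
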