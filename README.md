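# bundlekit3d

3D reconstruction and morphometry of cochlear stereocilia bundles from
per-frame 2D segmentation masks.

Cochlear hair cells carry V-shaped stereocilia bundles whose heights,
orientations and actin content vary systematically along the tonotopic axis
and are disrupted by deafness mutations. Confocal z-stacks of
phalloidin-stained cochleae capture these bundles in 3D, but most segmenters
(Mask R-CNN and friends) operate per 2D plane. `bundlekit3d` is a GUI-free,
weight-free library + CLI that takes any segmenter's per-plane instance
masks and

- **reconstructs 3D bundle instances** by greedy overlap tracking across
  planes: a detection joins the active track whose most recent mask it
  overlaps the most (ties and contested tracks resolved deterministically),
  otherwise it seeds a new instance;
- **measures each bundle**: 15 2D/3D region metrics, tip-to-base height
  `h = √((sx·Δx)² + (sy·Δy)² + (sz·Δz)²)` between the topmost projection
  pixel (tip) and the end of a downward trace from the projection centroid
  (base), with per-axis voxel scaling — a measure that follows the bundle
  through z and is therefore insensitive to in-plane rotation;
- **estimates bundle orientation** relative to the planar-cell-polarity
  axis from left/right anchor points and the peak of the z-projection
  (`atan2` baseline, axis and apex angles; two anchor rules for V-shaped
  and atypical bundles);
- **quantifies fluorescence per bundle** with three depth-aggregation
  modes (all layers / truncate to the common depth n = min dᵢ / pad to
  n_max = max dᵢ with the weakest layer), optional background subtraction
  and max normalization;
- **assigns row identity** (IHC, OHC1–3) by clustering base-point
  y-coordinates (KMeans or Gaussian mixture);
- **evaluates detection** against ground truth by volumetric IoU matching
  swept over thresholds 0.10…1.00, with F1 = 2TP/(2TP+FP+FN) and
  accuracy = TP/(TP+FP+FN) (so accuracy = F1/(2−F1));
- **computes texture phenotypes** (GLCM contrast/correlation/energy/
  homogeneity and 10-bin uniform LBP histograms) with Mann–Whitney
  group comparisons, plus focus-zone selection, stack rotation correction
  with padding-free cropping, and tonotopic majority voting around frame
  classifiers you plug in.

A seeded phantom generator (`bundlekit3d.phantoms`) draws V-shaped bundles
in four rows with complete ground truth — label volume, landmarks, heights,
angles, depths, per-layer occupancy — so the entire pipeline is testable
end-to-end without any image data.

## Worked example

```python
from bundlekit3d import evaluate, morphometry, phantoms, reconstruct, rows

cfg = phantoms.PhantomConfig(seed=42)              # 4 rows x 4 bundles, 30-plane stack
stack, gt, truth = phantoms.generate_stack(cfg)

# simulate an imperfect 2D segmenter: per-plane masks with 5% frame dropout
series = phantoms.degrade_to_frame_masks(gt, dropout_rate=0.05, seed=42)
vol = reconstruct.reconstruct_volume(series, stack.shape, max_gap=2,
                                     min_frames=2, min_voxels=20)

heights = morphometry.measure_heights(vol, cfg.voxel_size)
assignment = rows.row_assign(heights, method="gmm", seed=42)
sweep = evaluate.sweep_thresholds(gt, vol)
```

which prints (`heights.head(4)`, the row labels, and the IoU-0.5 sweep row):

```
reconstructed 16 of 16 bundles
 id  x1  y1  z1  x2  y2  z2  height_um
  1 234 149   3 252 175  26   2.872264
  2  58  74   3  76 100  26   2.872264
  3 324  74   3 342 100  26   2.872264
  4 323 299   3 307 325  26   2.850293
row identities: {1: 'OHC2', 2: 'OHC3', 3: 'OHC3', 4: 'IHC'}
 iou_threshold  tp  fp  fn  f1  detection_accuracy
           0.5  16   0   0 1.0                 1.0
```

Each height row stores the tip (x1, y1, z1) and base (x2, y2, z2) voxel
coordinates and the physical distance in µm (≈2.9 µm here, a mid-cochlear
scale); despite the dropped frames, gap-tolerant tracking recovers every
bundle exactly (F1 = 1.0 at IoU 0.5).

The same stages are available as a CLI for batch work:

```sh
bundlekit3d simulate --seed 42 --out sim/
bundlekit3d reconstruct --frames sim/frames --out labels.tif --max-gap 2
bundlekit3d measure --labels labels.tif --voxel 0.110,0.043,0.043 --out meas/
bundlekit3d rows --heights meas/heights.csv --method gmm --out rows.csv
bundlekit3d evaluate --gt sim/labels.tif --pred labels.tif --out eval.csv
bundlekit3d batch --config batch.json --out results/   # many samples, isolated failures
```

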