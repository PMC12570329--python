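# spinemorph

Dendritic spine morphometry, segmentation validation and longitudinal
tracking for 3-D fluorescence microscopy.

Dendritic spines — micron-scale protrusions carrying most excitatory
synapses — are quantified from volumetric images of sparsely labelled
neurons. Modern deep-learning segmenters emit multi-class label maps
(background / dendrite / soma / spine head / spine neck); everything that
has to happen *after* segmentation is what this package does:

* **Instance extraction** — connected components of the head∪neck
  foreground become individual spines, each attached to its nearest
  dendrite voxel, with volume/distance filters
  (defaults 0.035–2 μm³) to drop spurious detections.
* **Morphometry** — per spine: volume, head volume, centroid, spine
  length *L* (base → tip), neck length, head width (maximal inscribed
  sphere), distance to the shaft, and Euclidean vs geodesic distance to
  the soma, the geodesic being the shortest path constrained to the
  dendrite∪soma foreground. Per dendrite: skeleton length and spine
  density (spines/μm), with SWC export of the centreline tree. Every
  distance uses the physical voxel spacing — with 65 × 65 × 150 nm (or
  102 × 102 × 1000 nm) voxels, anisotropy is never ignored.
* **Validation** — Dice 2|A∩B|/(|A|+|B|) and IoU |A∩B|/|A∪B| per class;
  one-to-one object matching at an IoU threshold (default 0.5) giving
  TP/FP/FN, precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R);
  F1 curves over thresholds 0.1–0.9; anisotropic surface Hausdorff
  distances.
* **Tracking** — regularized phase-correlation rigid registration with
  sub-voxel refinement, instance matching across time points (IoU ≥ 0.3),
  and classification of each spine as stable, formed or eliminated with
  turnover percentages and paired volumes.
* **Phantoms** — a synthetic scene generator (tube-like shaft, ball soma,
  capsule necks, ball heads, with analytic ground truth) plus an imaging
  degradation model (anisotropic PSF blur → Poisson shot noise → read
  noise) and training-style augmentation, so the whole pipeline is
  testable end-to-end with no external data.

Restoration and segmentation models themselves are out of scope: the
package consumes their outputs as TIFF label maps.

## Worked example

```python
import spinemorph as sm

# generate a synthetic dendrite bearing 8 spines, imaged at the
# spinning-disk preset (65 x 65 x 150 nm voxels), then analyse it
spec = sm.straight_scene_spec(n_spines=8, shape=(32, 128, 256), seed=7)
volume, labels, gt_instances, gt = sm.generate_scene(spec)
noisy = sm.degrade(volume, sm.DegradeSpec(seed=7))

instances = sm.attach_all(sm.extract_spine_instances(labels), labels)
kept, rejected = sm.filter_spines(instances, sm.FilterSpec(), labels.spacing)
records = sm.measure_spines(kept, labels, noisy)
tree = sm.skeletonize_dendrite(labels)
summary = sm.summarize(records, tree, image_id="demo")

print(f"spines kept: {summary.spine_count}  (rejected: {len(rejected)})")
print(f"dendrite length: {summary.skeleton_length_um:.2f} um")
print(f"spine density: {summary.spine_density_per_um:.3f} per um")
```

prints

```
spines kept: 8  (rejected: 0)
dendrite length: 15.15 um
spine density: 0.528 per um
```

All 8 planted spines are recovered; the skeleton is shorter than the
16.6 μm image because the centreline collapses inside the soma. Each
record carries the full measurement set, e.g. the first spine reports
volume 0.259 μm³, length 1.60 μm, head width 0.72 μm and a soma distance
of 1.89 μm (Euclidean) vs 1.91 μm (geodesic) — near-equal on a straight
dendrite, while on a bent one the geodesic grows with the path.

## Command line

```sh
spinemorph phantom --preset spinning-disk --n-spines 10 --seed 1 --out scene/
spinemorph analyze --input scene/ --output results/ --spacing 0.15,0.065,0.065
spinemorph validate --pred pred_labels.tif --gt gt_labels.tif --iou 0.5
spinemorph track --t0 inst_day0.tif --t1 inst_day1.tif --min-iou 0.3
spinemorph swc-export --labels labels.tif --out tree.swc
```

`analyze` processes every `<stem>.tif` / `<stem>_labels.tif` pair in a
folder, writes per-spine CSVs, instance maps, MIP overlays, SWC
skeletons and a combined summary, and keeps going past per-image
failures (non-zero exit if any failed).

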