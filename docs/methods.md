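# Methods

This note documents the models, definitions and numerical choices behind
spinemorph, in the order the pipeline runs them.

## Data model and conventions

Images are 4-D arrays ordered `(channel, z, y, x)`; label maps are 3-D
`(z, y, x)` with class codes 0 background, 1 dendrite, 2 soma, 3 spine
head, 4 spine neck. Voxel spacing `(z, y, x)` in micrometres is supplied
by the user (TIFF resolution tags are too dialect-dependent to trust);
two presets cover the common regimes: spinning-disk confocal
(0.065 × 0.065 × 0.150 μm) and in-vivo two-photon
(0.102 × 0.102 × 1.0 μm, ~10× axial anisotropy). All distances,
volumes and path lengths are computed in physical units; voxel-count
shortcuts are never used because axial under-sampling would otherwise
bias every 3-D measurement. Exported coordinates (CSV, SWC) are
micrometres with the origin at the centre of voxel (0, 0, 0).

## Instance extraction

Spines are the connected components of the head∪neck foreground under
26-connectivity (default). 6-connectivity fragments thin necks at coarse
z-steps — a one-voxel diagonal step along an oblique neck disconnects
it — which is why the wide neighbourhood is the default. Touching spines
are not split; the upstream segmenter is responsible for instance
separation, and a watershed-style splitter is a documented extension
point. Components are numbered by decreasing size, ties broken by the
lexicographically smallest voxel, so numbering is deterministic. A spine
with neck but no head voxels is retained; its head-specific measurements
are reported as missing, never as zero.

The attachment point is the dendrite voxel nearest (anisotropic
Euclidean) to any voxel of the spine, computed from a single distance
transform of the dendrite complement; the spine-to-shaft distance is
that minimum. Filtering keeps a spine iff
`min_volume ≤ volume ≤ max_volume` and
`distance_to_dendrite ≤ max_distance`, with defaults 0.035 μm³, 2 μm³
and 1 μm; volume counts head∪neck voxels times the voxel volume. The
volume window follows the widely used spine-volume bounds for confocal
data; the distance cap is this package's own default (a real spine
touches the shaft, so 1 μm is generous and mainly guards against
floating debris). Rejected spines carry the violated rule name;
filtering is idempotent and kept spines are renumbered 1..K.

## Morphometry

**Skeleton.** The dendrite∪soma mask is thinned to a 1-voxel centreline
(3-D topological skeletonization), neighbouring skeleton voxels are
linked with anisotropic edge lengths, and a minimum spanning forest
removes redundant diagonal links before the tree is rooted. The root is
the skeleton voxel nearest the soma when one is present (class
precedence paints the shaft over the soma core, so proximity rather than
class membership decides), otherwise an endpoint of the longest path.
Node radii come from the interior distance transform. Dendrite length is
the sum of edge lengths; on straight-tube phantoms it is accurate to
well under 5% (endpoints are preserved by the thinning), while inside a
soma the centreline collapses, so whole-cell skeletons are shorter than
the image extent — spine density is therefore best measured on
shaft-only segments.

**Per-spine geometry.**

* *Spine length* — the maximum anisotropic distance from the attachment
  point to any spine voxel centre (base → tip). The alternative
  (base → head centroid) systematically under-reports long spines.
* *Head width* — twice the maximum of the anisotropic interior distance
  transform over head voxels: the maximal inscribed sphere diameter.
  Deterministic and anisotropy-aware; it under-estimates the true
  diameter by up to about half a voxel in the controlling direction,
  which is within the stated 15% tolerance for heads of radius
  ≥ 3 lateral voxels.
* *Neck length* — shortest path from the spine's base to the nearest
  head voxel, constrained to the instance's own voxels; 0 when the
  instance has no neck voxels, and measured to the farthest instance
  voxel when it has no head. Two numerical choices matter here. First,
  the step from the attachment voxel (which lies on or just inside the
  shaft surface) into the adjacent instance voxel is free, so the path
  is measured within the spine itself rather than from inside the
  shaft. Second, the shortest path runs on a 5×5×5 primitive-vector
  stencil (Dijkstra over the instance subvolume) instead of the 26
  unit moves: the 26-neighbour chamfer metric over-estimates oblique
  paths by up to ~17% on a 65/150 nm grid, the wide stencil brings that
  down to a few percent. The stencil's 2-voxel moves can cut a corner
  through a 1-voxel background notch; within a single convex-ish spine
  this is negligible and accepted.
* *Soma distances* — both the Euclidean and the geodesic distance are
  measured from the attachment point: the straight-line distance to the
  nearest soma voxel versus anisotropic distance propagation
  (minimum-cost path, unit cost on the dendrite∪soma foreground, seeded
  at every soma voxel) evaluated at the attachment. Using one reference
  point for both makes `geodesic ≥ euclidean` a theorem rather than a
  tendency; measuring the Euclidean leg from the spine centroid instead
  would break that guarantee for spines attached beside the soma. The
  geodesic propagation uses the 26-neighbour metric (its few-percent
  overshoot is conservative and it cannot jump gaps); a spine whose
  attachment is not connected to the soma through the foreground gets a
  missing geodesic, not a zero.

**Intensities.** Mean, max and integrated (sum × voxel volume)
intensity over the instance, per channel, on whatever image the caller
passes (raw or restored).

**Summaries.** Per dendrite: spine count, skeleton length, density
(count/length, missing for zero-length skeletons) and means of the
per-spine measurements, ignoring missing values.

## Validation

Pixel level: Dice and IoU per class, with the both-empty = 1.0
convention so phantom scenes lacking a class still produce a defined
report. Object level: all (pred, gt) pairs with IoU ≥ threshold are
candidates; greedy selection in descending IoU (ties: lower gt id, then
lower pred id) yields a one-to-one matching. Above threshold 0.5 an
instance can have at most one partner above threshold, so greedy
matching coincides with optimal assignment there (the tests confirm
agreement with a Hungarian oracle); below 0.5 it can diverge in
contrived overlap patterns — a trade made for determinism. F1 curves
over thresholds 0.1–0.9 are monotone non-increasing by construction
(raising the threshold restricts the greedy candidate list to a prefix).
Hausdorff distances are computed between 6-connectivity surface voxels
under the anisotropic metric, full maximum by default (the variant
matching "farthest mismatched boundary point" semantics) with an
optional 95th-percentile form.

## Tracking

Registration estimates a pure translation by phase correlation with
three robustness ingredients, each standard and deterministic: mean
subtraction plus a separable Hann window (suppresses circular-wraparound
correlation), spectral whitening with a noise floor of 0.5 × the mean
cross-power magnitude (pure whitening amplifies shot noise at
frequencies without signal; the floor interpolates toward matched-filter
correlation there), and a Gaussian band-limit so the correlation peak is
a symmetric ~1-voxel-sigma bump that a 3-point quadratic fit per axis
refines to sub-voxel precision. On phantom pairs at realistic SNR the
planted shift is recovered to better than 0.15 voxel. Constant images
are rejected.

Label maps are resampled with nearest-neighbour interpolation, images
tri-linearly; out-of-frame regions fill with background. Non-rigid
correction is deliberately an adapter: `apply_displacement_field`
consumes an externally computed dense offset field, and no deformable
registration engine is included.

Identity matching reuses the greedy IoU machinery at a default threshold
of 0.3 — lower than validation's 0.5 because genuine day-to-day
morphological change reduces overlap without implying a different
spine. Matched spines are stable and share a track id; unmatched
later-session spines are formed, unmatched earlier-session spines
eliminated. Rates: stable% and eliminated% are relative to the first
session's population, formed% to the second's. Longer series are chained
pairwise with track ids propagated forward.

## Phantom generator

Scenes are built from analytic solids voxelized on the target grid: a
capsule-swept tube for the shaft (default radius 0.4 μm), an optional
ball soma (default radius 1.5 μm), and per spine a cylindrical neck
(radius 0.1 μm) plus a spherical head, attached perpendicular to the
shaft. Class precedence at overlaps is head > neck > dendrite > soma.
Two rendering details keep the voxel geometry faithful to the analytic
ground truth: spine voxels are clipped to stay strictly outside the
shaft/soma surface (a neck must not eat into the shaft interior —
adjacency across the surface keeps the spine attached), and the head
ball overlaps the neck end by one minimum-spacing unit so the two are
always voxel-connected; the gt table records the rendered,
overlap-corrected neck and spine lengths.

Default spine geometry is realistic for cortical pyramidal neurons:
head radii 0.25–0.4 μm (volumes ≈ 0.07–0.27 μm³, inside the 0.035–2 μm³
analysis window), neck lengths 0.7–1.3 μm. Two sampling realities shape
the defaults. Necks much shorter than ~0.5 μm are not planted: a
voxel-centre path measurement carries a ±1-voxel (~±0.08 μm at the
spinning-disk preset) floor at each end, so such necks cannot be
length-recovered to 15% by any estimator — the same resolution limit
applies to the instrument itself. And spines are planted within ~30° of
the lateral plane, alternating sides of the shaft (so neighbours never
merge); axially projecting spines are unresolvable at coarse z-steps
and are routinely excluded from analysis in real datasets. At z-steps
too large to sample the smallest head off-plane (the two-photon preset),
spines stay in the focal plane entirely and the shaft is placed on a
voxel-centre z-plane, an in-focus dendrite. With these conditions the
round trip (generate → extract → measure) recovers spine counts exactly
and head volumes/neck lengths typically within 15% of the analytic
values; occasional worst-case draws can put a single short neck a few
points above that, which is the discretization floor, not estimator
bias.

Degradation chains an elongated anisotropic Gaussian PSF (defaults:
σ_lateral 0.08 μm, σ_axial 0.25 μm), Poisson shot noise via draw at
`intensity × photon_scale` then rescale — making `photon_scale` the
single SNR knob (default 0.2, i.e. ~40 detected photons at the default
foreground intensity; `None` disables) — and additive Gaussian read
noise (default σ 2). The zero-blur, no-shot-noise, zero-read-noise limit
is exactly the identity. Degradation acts on intensities only; labels
are generated, never re-derived, so ground truth is exact by
construction. Augmentation offers right-angle z-rotations, per-axis
flips, shot noise and Gaussian blur; geometric ops transform image and
labels identically (labels stay hard values), noise ops touch the image
only. Arbitrary-angle rotation is rejected because it would force label
interpolation choices with no principled hard-label answer.

## Pipeline, determinism and problem sizes

`run_analysis` pairs `<stem>.tif` with `<stem>_labels.tif`, optionally
resamples to an analysis spacing (nearest-neighbour for labels), and
writes all outputs at the original resolution; unmatched images are
skipped with a warning and per-image failures are isolated. Given
identical inputs, config and seed, all data outputs (CSV, TIFF, PNG,
SWC, YAML) are byte-identical across runs; only the run log, which
timestamps events, differs. Overlay colours come from golden-ratio hue
stepping seeded by the config.

The test suite and the acceptance script exercise scenes up to
256 × 256 × 64 voxels with 10–20 spines — large enough that every
feature spans many voxels in all axes, while a full analysis of such a
scene completes in seconds. The acceptance script derives every
reported number by running the pipeline on scenes it generates itself
at run time.

## Known limitations

* Instances are hard labels; probability-map thresholding is out of
  scope, as are the restoration/segmentation networks themselves.
* Touching spines remain single instances (no watershed splitting).
* Head width and neck length are stand-in definitions (inscribed
  sphere; base-to-head shortest path) chosen for determinism and
  anisotropy-awareness; other conventions exist in the literature.
* Spine density uses skeleton length, which collapses inside somata;
  density on whole-cell images should be read per shaft segment.
* Registration is translation-only; rotation/scale drift and
  deformation require the external displacement-field adapter.
* No spine classification (stubby/mushroom/thin) is attempted.
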