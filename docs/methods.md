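# Methods

## Scope and model

`glioprofile` operates downstream of segmentation and registration: its input
is a binary (or probabilistic) tumor mask already aligned to a common
reference space, together with an atlas bundle in that space. The package
models the tumor as a set of foreground voxels on a regular lattice with an
invertible voxel-to-world affine; all physical quantities (volumes in mL,
distances in mm) are derived through that mapping. Voxel indices are 0-based
and world coordinates refer to voxel centres. The distance operators read the
spacing off the affine column norms and therefore assume an axis-aligned
mapping — the standard situation for masks resampled into a reference frame.

## Mask refinement

Automatic segmentations carry speckle noise, so feature extraction starts
with a refinement pass: binary closing with a spherical voxel kernel of
radius 2 (offsets with Euclidean index norm ≤ 2), applied for two iterations,
followed by removal of connected components smaller than 0.1 mL. The kernel
radius is in voxels, not mm, because refinement runs after registration to a
~1 mm isotropic frame where the two coincide. The lattice is zero-padded
before closing so the operation is extensive (it never removes an input
voxel) even at the volume border. The 0.1 mL floor is strict ("smaller
than"): a component of exactly 0.1 mL survives.

## Feature definitions and conventions

* **Volume** — voxel count × voxel volume / 1000 (mL), reported in both the
  native patient geometry and the reference geometry.
* **Laterality** — per-voxel left/right assignment from the hemisphere mask;
  percentages of tumor voxels per side (summing to 100), and a crossing flag
  when at least one voxel lies strictly on each side. Voxels exactly on the
  midline plane belong to the left hemisphere; crossing still requires a
  voxel on each side.
* **Multifocality** — 26-connected components (the common convention for 3D
  lesion analysis; configurable to 6 or 18). The biggest focus is the one of
  maximal volume; equivalent-sphere diameters `(6V/π)^{1/3}` are retained as
  auxiliary output only. A secondary component qualifies as an independent
  satellite focus only when its minimum surface distance to the biggest
  focus is ≥ 5.0 mm; closer components are not counted and do not contribute
  to the reported distance, but they stay in the mask and keep contributing
  to volume and overlap features. The reported distance is the largest
  minimum distance from the biggest focus to any qualifying satellite;
  unifocal tumors report the −1.0 mm sentinel.
* **Resectability** — the heat map of the hemisphere holding the larger
  share of the tumor is integrated over the tumor voxels:
  `resectable = Σ p(v) · v_vox / 1000` (mL); the expected residual is the
  tumor volume minus the resectable volume and the index is their ratio,
  clipped to [0, 1]. An exact 50/50 laterality tie selects the left map
  (deterministic; such ties are measure-zero in practice).
* **Cortical profile** — for each structure of the four parcellations
  (15 + 48 + 7 + 17 = 87 structures), `100 · |T ∩ S| / |T|`. Structures
  within one parcellation are disjoint, so each atlas's overlaps sum to at
  most 100.
* **Subcortical profile** — each of the 68 probabilistic structures is
  binarized at p ≥ 0.5 (inclusive, so a probability of exactly 0.5 is
  inside). Overlapping structures report distance 0.0; structures empty
  after thresholding report the −1.0 sentinel; otherwise the directed
  95th-percentile distance from tumor boundary voxels to the structure is
  reported. The direction (tumor → structure) describes how far the tumor
  sits from the tract and is robust to boundary outliers; a plain-minimum
  variant is available through `min_surface_distance`.

Feature names are namespaced `category.atlas.structure` to guarantee global
uniqueness; the record always carries 233 = 2 + 3 + 3 + 2 + 87 + 2·68 named
values in a stable order. A mask that is empty after refinement yields an
explicit "no tumor" record variant rather than silent zeros.

## Distance computations

Surface voxels are foreground voxels with a 6-neighbourhood background
neighbour (lattice borders count as background). Directed surface distances
are computed with an exact Euclidean distance transform sampled at the
source's surface voxels; HD95 is the maximum of the two directed 95th
percentiles (linear-interpolation percentile), the most common symmetric
convention. `min_surface_distance` is the minimum world distance between any
voxel centres of the two masks and is 0 on overlap. On lattices up to 12³
all of these match O(n²) brute-force pairwise oracles to machine precision
(enforced in the test suite and the acceptance script).

## Validation metrics

* **Threshold sweep** — probability maps are binarized at p ≥ t for ten
  equally spaced thresholds; the default sweep uses the bin centres
  0.05, 0.15, …, 0.95, avoiding the degenerate endpoints 0 and 1
  (configurable). Dice of two empty masks is defined as 1.0 (agreement on
  absence); HD95 is undefined for empty masks and reported as NaN, and
  cohort aggregation skips undefined cases.
* **Object detection** — connected components of both masks below 50 voxels
  are discarded; candidate (ground-truth, prediction) pairs are matched
  greedily by descending voxel overlap, one-to-one, with ties broken by
  component label order. A ground-truth tumor is a true positive when its
  pairing Dice is ≥ 0.25. False positives are the prediction components left
  without a pairing; a paired prediction below the Dice threshold is a
  missed detection rather than an extra object. Dice-TP averages Dice over
  detected tumors only. Recall/precision are NaN when there are no
  ground-truth objects / no predictions. A many-to-one merge mode was
  considered and left out: one-to-one greedy matching is deterministic and
  reproducible, which matters more here than squeezing out edge-case
  detections.
* **Pooled estimates** — with fold sizes n_i, means m_i and SDs s_i
  (ddof = 1): N = Σn_i, M = Σn_i·m_i/N and
  S² = [Σ(n_i−1)s_i² + Σn_i(m_i−M)²]/(N−1), which reproduces the sample
  mean/SD of the concatenated per-patient values exactly.
* **Consensus** — a voxel belongs to the consensus mask when at least half
  of the raters annotated it; with an even rater count "at least half" means
  ≥ R/2 exactly, so 4 of 8 suffice.

## Synthetic data

The generator is a pure function of (spec, seed) via `numpy`'s Philox-seeded
`default_rng`, and emulates the *structure* of the real inputs, not their
appearance:

* **Bundle** — a lattice centred on the world origin (default 48³ at 1 mm;
  small enough that the full pipeline and its 68 distance transforms run in
  well under a second per case, large enough to host all structure counts);
  hemisphere mask split at the world mid-plane; four disjoint box-grid
  parcellations with the required 15/48/7/17 structures; 68 subcortical
  structures with linearly decaying radial probability profiles (random
  centres and radii of 5–9 mm, bilateral tracts mirrored through the
  mid-plane: 28 left/right pairs + 12 midline singletons = 40 base names);
  per-hemisphere heat maps decaying linearly with distance from the
  hemisphere centroid.
* **Phantoms** — voxelized spheres at requested world centres/radii; the
  soft map is the Gaussian-blurred mask (σ = 1.5 voxels) rescaled to peak 1;
  rater variants toggle voxels of the one-voxel boundary shells with the
  `rater_noise` probability, so consensus voting has a meaningful gradient.
  `random_phantom_spec` draws one main focus (radius ≥ 5 mm) and, with
  probability 0.5, a satellite of 3–4.5 mm radius placed so its surface gap
  to the main focus exceeds the 5 mm rule; the satellite radius floor keeps
  its volume above the 0.1 mL refinement threshold.
* **Truth** — recorded from the voxelized lattice by direct counting and
  exact pairwise KD-tree distances, independent of the feature operators, so
  recovery tests are exact (laterality, focus rules, overlaps) or near-exact
  (volume within one voxel volume, resectability within 1e-6).

What passing these tests shows: the rules and arithmetic of the feature
computation are implemented correctly. What they do not show: performance on
clinical MRI, where registration error, non-spherical infiltrative shapes
and segmentation noise dominate — none of which the phantoms emulate.

## Numerical choices and degenerate inputs

Empty masks are rejected explicitly (`EmptyMaskError`) by operators whose
result would be undefined, and tolerated where a sensible value exists
(empty∩empty Dice = 1, empty refinement output → "no tumor" record).
Geometry agreement is enforced with a 1e-5 affine tolerance. Resampling is
nearest-neighbour through world coordinates (banker's rounding at exact
half-voxel positions), with out-of-source voxels set to background. CSV
output keeps full float precision; the text report rounds percentages, mL
and mm to two decimals and the resectability index to four.

## Known limitations

* Real published atlases (MNI structural, Harvard-Oxford, Schaefer 7/17,
  the probabilistic subcortical atlas, resection heat maps) are supported
  through the documented bundle layout but not shipped; structure name
  tables and heat-map normalization are treated as data.
* No registration: masks must already live in the bundle geometry (only a
  nearest-neighbour resampler is provided). No DICOM ingestion.
* Distance operators assume axis-aligned affines; sheared or oblique
  geometries should be resampled first.
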