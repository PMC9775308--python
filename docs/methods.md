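# Methods

## Image model and containers

All volumes are carried as `VoxelGrid`: a non-negative 3D intensity array in
`(z, y, x)` order with physical voxel dimensions `(dz, dy, dx)` in µm. The
default geometry is 0.7 × 0.7 µm laterally and 3 µm axially — the common
confocal z-stack setting for cleared skin constructs — so the axial sampling
is ~4× coarser than lateral. Every physical measurement (thickness, diameter,
distance) is computed in µm with the true anisotropic sampling; nothing
assumes cubic voxels. TIFF pages map to z. Segmentations are `BinaryVolume`
masks aligned to their source grid.

Analysis proceeds on sub-volume tiles (`extract_subvolumes`): non-overlapping
tiles of a physical XY size laid contiguously along x and centred in the
field, keeping full depth — mirroring how adjacent confocal positions tile a
strip across a specimen. Per-sample values aggregate over tiles: thickness
pools columns, integrated intensity and the vascular metrics average per-tile
values.

## Plane-wise preprocessing

All spatial filters operate strictly within XY planes (median filter,
rolling-ball background, disk morphology), because structures of interest are
laterally resolved but only coarsely sampled axially; cross-plane filtering
would smear layer boundaries by multiples of 3 µm. Edges are reflect-padded,
so tile borders do not acquire dark rims; the compound morphology pads by
2r + 2 because the border effect of closing-then-opening reaches 2r inward.

Intensity rescaling maps chosen percentiles onto [0, 1] and clips; the
segmentation thresholds are then *fractions of the volume maximum*, making
the chain invariant to global intensity scale (a property the tests assert).
Hysteresis thresholding keeps voxels ≥ low·max that are 26-connected in 3D to
a voxel ≥ high·max; 26-connectivity is deliberately permissive so structures
remain linked across the coarse z-steps.

### Guarded background subtraction

A rolling ball estimates background as the envelope a ball of radius r traces
under the intensity surface. This is well-posed only when the structures to
keep are *narrower* than the ball: a stained layer spanning a whole plane at
near-uniform brightness is itself tracked by the ball and would be subtracted
to zero. Since epidermal and adipose scenes legitimately contain plane-wide
layers, `preprocess_channel` guards the step: the confident foreground
(voxels at or above the hysteresis seed level) is compared before and after
subtraction, and if fewer than half of those voxels survive, the subtraction
is judged to have removed the structure itself and the unsubtracted channel
is used. The guard threshold (0.5) is a coarse switch, not a tuning knob: in
the scenes exercised here the survival fraction is near 1 when subtraction is
appropriate and near 0 when it is not. The ball radius is clamped to half the
plane extent for small tiles (the primitive itself rejects balls larger than
the plane).

Defaults (`FilterParams`): median radius 1 px, rolling-ball radius 50 px,
hysteresis 0.2/0.5 of max, disk radius 4 px. These are implementation
choices, configurable via a JSON `filters` block; no published values exist
for them.

## Epidermal thickness

The three marker channels are preprocessed independently and fused by
voxelwise maximum — the stains jointly localize the epidermis (nuclei
throughout the living layers, cytokeratin 10 suprabasally, involucrin
cornified), so the union of their domains is the layer. Thickness is
per-column: `(z_top − z_bottom + 1) × dz` over the outermost extents, the
voxel-count convention, so a one-plane layer reads dz rather than 0. Columns
with no signal are invalid and excluded from summaries. Internal gaps are
expected to be closed by the morphology; remaining gaps are bridged by using
outermost extents. Pooled-column mean/median is the default summary; a
per-tile-first average is available (`per_tile=True`) — the two differ when
tiles have unequal valid areas.

## Adiposity

Three readouts with deliberately different sensitivities:

- **Lipid VF** — voxel fraction of the droplet mask over the full sub-volume
  (the denominator is the imaged volume, not a tissue-restricted region).
- **Adipose thickness** — the droplet mask is closed with a larger disk
  (default 8 px) to bridge inter-droplet gaps into a layer, then measured
  exactly like epidermal thickness (pooled column mean).
- **Integrated intensity** — the sum of *raw* (unfiltered) channel intensity
  over masked voxels, averaged across sub-volumes. Raw intensity keeps the
  readout linear in lipid content; the mask only isolates stain from
  background.

Because segmentation is intensity-scale invariant, halving droplet brightness
at fixed geometry leaves VF and thickness essentially unchanged while halving
integrated intensity — the mechanistic signature separating lipid loss from
adipocyte loss, reproduced end-to-end in the acceptance tests.

## Vascular morphometry

- **Vesselness**: volumes are linearly resampled to an isotropic grid at the
  finest voxel dimension (Hessian scales must be physically round), the
  Frangi tubularity response evaluated at each physical scale (default 2, 4,
  6, 8, 10 µm; α = β = 0.5, structureness cutoff at half the maximum Hessian
  norm) with the voxelwise maximum over scales, then resampled back.
- **Segmentation**: hysteresis on the response plus removal of components
  below a voxel-count floor. The thresholded response detects *where* tubes
  run but misstates caliber (the response decays inside the lumen boundary
  and can ring outside it at coarse scales), so `extract_network` by default
  refines the mask against the raw channel: intensity-threshold components
  (26-connected, ≥ 0.2 of channel max) that contain detected core voxels are
  kept. Detection by geometry, delineation by stain.
- **Skeleton**: topology-preserving 3D thinning. One degenerate case is
  handled explicitly: a digital cylinder whose axis falls exactly between
  voxel centers in both lateral axes has no unique center voxel and thinning
  annihilates it; such components fall back to a deterministic EDT-ridge
  centerline (deepest voxel per slice along the component's longest axis).
  The fallback only triggers on synthetically perfect tubes.
- **Diameters**: the anisotropy-aware EDT of the mask (distance in µm to the
  nearest background voxel center) sampled along the skeleton, × 2. The
  center-to-center convention biases small structures up: an isolated voxel
  reads one voxel-unit of radius. On digitized cylinders the recovered median
  diameter is within ~10% of truth for axis-centered tubes and within 25%
  for between-voxel axes (the corner-voxel centerline reads √(r²−Δ²)-type
  distances); the radius ordering is always preserved.
- **R_k (diffusion length)**: the EDT of the background to the nearest vessel
  voxel; R_k is the 0.90 quantile (linear interpolation over background
  voxels only — vessel voxels are excluded, so R_k is a property of the
  tissue, not diluted by network volume at high VF). Validated to machine
  precision against an exhaustive O(N²) nearest-vessel search on volumes up
  to 32³, isotropic and anisotropic. R_k is antitone in the vessel set and
  VF monotone, both asserted as property tests.

## Phantom generator

The generator rasterizes scenes in physical µm space with voxel-center
sampling so that anisotropy errors are visible to tests. It emulates: a
z-contiguous epidermal slab whose per-column thickness is a laterally
smoothed, re-standardized Gaussian field (defaults 90 ± 5 µm, 3 µm surface
roughness — the scale of real construct epidermis) with punctate nuclei;
tubular vessels as solid capsules around polylines of exact radius; lipid
droplets as rejection-sampled non-overlapping spheres confined to a basal
layer (defaults 30 droplets of 5–10 µm radius); plus additive corruption
(smooth background ramp, sparse Gaussian autofluorescent blobs, pixelwise
Gaussian noise, clipped at zero). Every output is a pure function of
(spec, seed).

`PhantomTruth` stores the geometry actually rasterized — per-column voxel
extents, voxel-exact volume fractions, axis polylines, analytic sphere
volumes — with no re-measurement, so measurement error and rasterization
error are separable: VF against the truth *mask* must match exactly, VF
against the *analytic* volume only within discretization error (≤ 5% for
radii ≥ 4 voxels).

What the phantoms do **not** model: the confocal point-spread function,
depth-dependent attenuation, clearing artifacts, spectral bleed-through, and
shot-noise statistics (noise is additive Gaussian). Passing tests therefore
demonstrate correctness of the measurement chain on geometrically faithful
scenes, not robustness to every optical artifact of real acquisitions.

## Dosimetry and statistics

Radiant exposure: daily J/cm² = irradiance mW/cm² × exposure seconds / 1000,
exact until display; totals multiply by days; the irradiance meter tolerance
is carried as an optional min/max interval but not propagated into
statistics. Group comparisons divide every sample by the control-group mean
(controls normalize to mean 1), then a two-tailed unpaired t-test for two
groups — pooled variance by default, Welch by flag — or one-way ANOVA with
Tukey HSD pairwise p-values for more. Identical zero-variance groups return
t = 0, p = 1 rather than an error.

## Problem sizes and numerical choices

Validation runs use sub-volumes of 64²–128² lateral voxels and 40–128
planes, tube phantoms at 128³ isotropic voxels, and 12–30 random masks up to
32³ for the oracle cross-checks — sizes at which brute-force oracles are
exhaustive and every pipeline completes in seconds on one core. Rolling-ball
backgrounds for radii > 16 px are estimated on a proportionally downsampled
plane and upsampled back (the standard acceleration; the ball cannot follow
detail finer than its own radius, so the approximation is benign). Quantiles
use NumPy's linear interpolation. Ties in the EDT-ridge fallback break to the
first voxel in scan order. Degenerate inputs (constant volumes, empty masks)
return the documented neutral values with warnings rather than raising,
except where a quantity is genuinely undefined (R_k of an empty vessel set).

## Known limitations

- The thinning-based skeleton erodes ~3 voxels at open tube ends; skeleton
  length is bounded below but not exactly the axis length.
- Diameter estimates inherit digitization bias (±1 voxel-unit) and the
  small-structure bias of the center-to-center EDT convention.
- The over-subtraction guard is binary per channel; scenes containing *both*
  a plane-wide layer and dim sparse features in one channel will keep the
  background under the layer.
- The epidermal exactness guarantee (thickness = n_planes × dz through the
  full chain) holds for uniform slabs; rough slabs recover the median within
  one z-step, since plane-wise filters legitimately move staircase column
  boundaries by a voxel.
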