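# skinquant

Volumetric morphometry for engineered human skin constructs imaged by
multi-channel confocal microscopy.

Skin equivalents built with epidermal, vascularized-dermal, and hypodermal
adipose compartments are quantified from 3D image stacks rather than single
cross-sections. `skinquant` implements the three measurement pipelines such
studies rely on, plus the exposure arithmetic and statistics used to compare
control against UVA-photoaged cultures, and a synthetic phantom generator
that provides exact ground truth for validating every measurement.

**Epidermis** — the three epidermal marker channels (nuclear stain,
cytokeratin 10, involucrin) are median-filtered per XY plane, linearly
rescaled, background-corrected with a rolling-ball filter, fused by voxelwise
maximum, segmented by hysteresis thresholding, and cleaned with disk
closing/opening. Per-column thickness is read from the binary volume as
*(z_top − z_bottom + 1) · dz* µm, giving a volumetric thickness map; marker
expression is the mean of pooled z-maximum projections.

**Hypodermal adipose** — lipid-stain (BODIPY-type) droplets are segmented by
the same plane-wise chain; three readouts are computed: lipid volume fraction
VF (voxels in droplets / voxels total), adipose-layer thickness after a
morphological closing bridges droplets into a layer, and the integrated raw
stain intensity inside the mask. The intensity readout is linear in lipid
content at fixed geometry, so it dissociates lipid loss from droplet loss.

**Vasculature** — the collagen-IV basement-membrane channel is enhanced with
a multiscale Hessian vesselness (Frangi) filter on an isotropically resampled
grid, segmented, delineated from the raw intensity, and skeletonized by 3D
thinning. Per-point diameters are 2 × the anisotropy-aware Euclidean distance
transform sampled along the skeleton. The diffusion length

&nbsp;&nbsp;&nbsp;&nbsp;*R_k* = 90th percentile of { dist(x, nearest vessel voxel) : x ∈ tissue }

is the radius within which 90% of the tissue volume lies; lower *R_k* means
denser vascularization.

**Dosimetry and statistics** — radiant exposure in J/cm² from irradiance
(mW/cm²) × daily exposure seconds / 1000, totals over the schedule;
per-sample metrics normalized to the control-group mean; two-tailed t-test
for pairs, one-way ANOVA + Tukey HSD for more groups, with `*`/`**`
significance at 0.05/0.01.

## Worked example

```bash
python examples/epidermal_thickness.py
```

builds a ~90 µm synthetic epidermis at the standard 0.7 × 0.7 × 3 µm voxel
size, corrupts it with 10%-of-signal noise, a background gradient and
autofluorescent blobs, and runs the full measurement chain:

```
true median thickness     : 90.0 µm
recovered median thickness: 93.0 µm
recovered mean thickness  : 92.1 µm
valid columns             : 100%
K10 marker intensity (max projection mean): 1.280 a.u.
```

The recovered median is within one 3 µm z-step of the generator's truth — the
resolution limit set by the axial sampling. The other examples
(`vascular_network.py`, `adipose_quantification.py`, `dose_and_statistics.py`,
`full_scene.py`) exercise the remaining pipelines the same way; each prints
the measured values next to the phantom's ground truth.

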