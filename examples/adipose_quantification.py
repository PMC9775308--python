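"""Lipid morphometry and the intensity/morphology dissociation.

Generates a hypodermal droplet field twice — once at full stain brightness,
once at half — with identical droplet geometry, and quantifies both with the
three adiposity readouts.  Integrated intensity halves; volume fraction and
adipose thickness stay put: lipid loss without droplet loss.
"""

import skinquant as sq


def build(intensity):
    spec = sq.PhantomSpec(
        shape_vox=(40, 96, 96),
        voxel_size=(1.0, 1.0, 1.0),
        droplets=sq.DropletFieldSpec(
            n=8, radius_range_um=(5.0, 8.0), intensity=intensity,
            layer_z_range_um=(0.0, 40.0),
        ),
        seed=3,
    )
    lipid, truth = sq.make_adipose_phantom(spec)
    return sq.apply_noise(lipid, sq.NoiseSpec(gaussian_sd=0.02), 55), truth


bright, truth = build(1.0)
dim, _ = build(0.5)

res_full = sq.analyze_adipose([bright])
res_half = sq.analyze_adipose([dim])

print(f"true lipid VF            : {truth.lipid_vf:.4f}")
print(f"measured lipid VF        : {res_full.lipid_vf:.4f}  (half-intensity: {res_half.lipid_vf:.4f})")
print(f"adipose thickness        : {res_full.adipose_thickness_um:.1f} µm  "
      f"(half-intensity: {res_half.adipose_thickness_um:.1f} µm)")
ratio = res_half.integrated_intensity_au / res_full.integrated_intensity_au
print(f"integrated intensity ratio (half/full): {ratio:.3f}")
print("the morphological readouts are intensity-invariant; only the")
print("integrated intensity tracks lipid content per droplet")
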