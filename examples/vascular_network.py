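"""Vessel segmentation, skeleton diameters and diffusion length R_k.

Rasterizes a small vessel network of known radii, runs the multiscale
vesselness chain (Frangi detection, intensity delineation, 3D thinning, EDT
diameters) and reports the three vascular metrics.  R_k is the radius within
which 90% of the tissue volume lies; lower R_k = denser vascularization.
"""

import numpy as np

import skinquant as sq

tubes = [
    sq.VesselTubeSpec(np.array([[30.0, 20.0, 0.0], [30.0, 20.0, 96.0]]), radius_um=5.0),
    sq.VesselTubeSpec(np.array([[60.0, 70.0, 0.0], [60.0, 70.0, 96.0]]), radius_um=3.0),
    sq.VesselTubeSpec(np.array([[0.0, 48.0, 48.0], [96.0, 48.0, 48.0]]), radius_um=4.0),
]
spec = sq.PhantomSpec(shape_vox=(96, 96, 96), voxel_size=(1.0, 1.0, 1.0),
                      vessels=tubes, seed=2)
col4, truth = sq.make_vessel_phantom(spec)

network = sq.extract_network(col4)
result = sq.vascular_metrics(network)

print(f"true VF             : {truth.vessel_vf:.4f}")
print(f"measured VF         : {result.vascular_vf:.4f}")
print(f"median diameter     : {result.median_diameter_um:.2f} µm "
      f"(true radii {sorted(truth.vessel_radii_um)} µm)")
print(f"R_k (90% coverage)  : {result.rk_um:.1f} µm")
print(f"skeleton points     : {len(network.skeleton_points)}")
print("R_k under ~200 µm indicates spacing compatible with diffusive supply")
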