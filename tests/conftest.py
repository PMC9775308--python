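import numpy as np
import pytest

import skinquant as sq


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def uniform_slab_phantom():
    """Noiseless 30 µm (10-plane) uniform slab with exact truth."""
    spec = sq.PhantomSpec(
        shape_vox=(14, 48, 48),
        epidermis=sq.EpidermisLayerSpec(30.0, 0.0, 0.0, 1.0),
        seed=1,
    )
    return spec, sq.make_epidermis_phantom(spec)


@pytest.fixture(scope="session")
def noisy_slab_phantom():
    """Rough 90 ± 5 µm slab corrupted with 10%-of-signal noise, ramp and blobs."""
    spec = sq.PhantomSpec(
        shape_vox=(45, 64, 64),
        epidermis=sq.EpidermisLayerSpec(90.0, 5.0, 3.0, 1.0),
        noise=sq.NoiseSpec(
            gaussian_sd=0.1, background_ramp_amplitude=0.15, autofluor_blob_density=0.02
        ),
        seed=11,
    )
    clean = sq.make_epidermis_phantom(spec)
    noisy = tuple(
        sq.apply_noise(g, spec.noise, 101 + i) for i, g in enumerate(clean[:3])
    )
    return spec, noisy, clean[3]


@pytest.fixture(scope="session")
def tube_phantom():
    """Single straight 5 µm-radius tube in an isotropic 1 µm grid."""
    spec = sq.PhantomSpec(
        shape_vox=(40, 40, 80),
        voxel_size=(1.0, 1.0, 1.0),
        vessels=[
            sq.VesselTubeSpec(np.array([[20.0, 20.0, 0.0], [20.0, 20.0, 80.0]]), 5.0)
        ],
        seed=2,
    )
    return spec, sq.make_vessel_phantom(spec)


@pytest.fixture(scope="session")
def droplet_phantom():
    """Eight non-overlapping lipid spheres (r 5-8 µm) in an isotropic grid."""
    spec = sq.PhantomSpec(
        shape_vox=(40, 96, 96),
        voxel_size=(1.0, 1.0, 1.0),
        droplets=sq.DropletFieldSpec(8, (5.0, 8.0), 1.0, (0.0, 40.0)),
        seed=3,
    )
    return spec, sq.make_adipose_phantom(spec)
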