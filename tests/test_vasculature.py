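import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skinquant as sq
from skinquant.vasculature import refine_by_intensity


def brute_force_radius(mask, point, voxel_size):
    """Nearest-background search: the independent diameter oracle."""
    bg = np.argwhere(~mask) * np.asarray(voxel_size)
    p = np.asarray(point) * np.asarray(voxel_size)
    return np.sqrt(((bg - p) ** 2).sum(axis=1)).min()


class TestVesselness:
    def test_tube_centerline_dominates_background(self, tube_phantom):
        _, (col4, truth) = tube_phantom
        v = sq.vesselness(col4, scales_um=[3, 5, 8])
        centerline = v.data[20, 20, 10:70].mean()
        background = v.data[~truth.mask.mask].mean()
        assert centerline > 10 * max(background, 1e-12)
        assert v.data.min() >= 0 and v.data.max() <= 1

    def test_constant_volume_zero_response(self):
        g = sq.VoxelGrid(np.full((20, 20, 20), 3.0), (1, 1, 1))
        v = sq.vesselness(g, scales_um=[2, 4])
        assert np.all(v.data == 0)

    def test_blob_suppressed_relative_to_tube(self):
        # equal-radius sphere vs tube: the blob term must damp the sphere
        shape, vs = (40, 40, 40), (1.0, 1.0, 1.0)
        zz, yy, xx = np.meshgrid(*[np.arange(40) + 0.5] * 3, indexing="ij")
        sphere = ((zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 36).astype(float)
        tube = ((zz - 20) ** 2 + (yy - 20) ** 2 <= 36).astype(float)
        v_sphere = sq.vesselness(sq.VoxelGrid(sphere, vs), scales_um=[6])
        v_tube = sq.vesselness(sq.VoxelGrid(tube, vs), scales_um=[6])
        assert v_sphere.data[20, 20, 20] < 0.5 * v_tube.data[20, 20, 20]

    def test_empty_scale_list_rejected(self):
        g = sq.VoxelGrid(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            sq.vesselness(g, scales_um=[])


class TestSegmentVessels:
    def test_zero_response_empty_mask(self):
        v = sq.VoxelGrid(np.zeros((10, 10, 10)), (1, 1, 1))
        m = sq.segment_vessels(v, 0.05, 0.2, 10)
        assert not m.mask.any()

    def test_single_tube_single_component(self, tube_phantom):
        _, (col4, _) = tube_phantom
        v = sq.vesselness(col4, scales_um=[3, 5, 8])
        m = sq.segment_vessels(v, 0.2, 0.5, 20)
        from scipy import ndimage as ndi

        _, n = ndi.label(m.mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_speckles_removed_by_size_filter(self):
        data = np.zeros((20, 20, 40))
        data[8:13, 8:13, 5:35] = 1.0  # a chunky tube, >20 voxels
        rng = np.random.default_rng(6)
        for _ in range(5):
            z, y, x = rng.integers(0, 20), rng.integers(0, 20), rng.integers(0, 40)
            if data[z, y, x] == 0:
                data[z, y, x] = 1.0
        v = sq.VoxelGrid(data, (1, 1, 1))
        m = sq.segment_vessels(v, 0.3, 0.6, min_size_vox=20)
        from scipy import ndimage as ndi

        _, n = ndi.label(m.mask, structure=np.ones((3, 3, 3)))
        assert n == 1


class TestSkeletonize:
    def test_one_voxel_line_is_its_own_skeleton(self):
        m = np.zeros((5, 5, 30), bool)
        m[2, 2, 2:28] = True
        pts = sq.skeletonize(sq.BinaryVolume(m, (1, 1, 1)))
        assert len(pts) >= 24
        assert all(m[tuple(p)] for p in pts)
        assert np.all(pts[:, 0] == 2) and np.all(pts[:, 1] == 2)

    def test_cylinder_skeleton_near_axis(self):
        spec = sq.PhantomSpec(
            shape_vox=(20, 20, 50),
            voxel_size=(1, 1, 1),
            vessels=[sq.VesselTubeSpec(np.array([[10.0, 10.0, 0], [10.0, 10.0, 50]]), 4.0)],
        )
        _, truth = sq.make_vessel_phantom(spec)
        pts = sq.skeletonize(truth.mask)
        assert len(pts) >= 45
        lateral = np.abs(pts[:, :2] + 0.5 - 10.0)  # voxel centers vs axis in µm
        assert lateral.max() <= 1.0

    def test_two_disjoint_tubes_two_components(self):
        m = np.zeros((20, 20, 30), bool)
        m[4:7, 4:7, 2:28] = True
        m[13:16, 13:16, 2:28] = True
        pts = sq.skeletonize(sq.BinaryVolume(m, (1, 1, 1)))
        assert (pts[:, 0] < 10).any() and (pts[:, 0] > 10).any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sq.skeletonize(sq.BinaryVolume(np.zeros((3, 3, 3), bool), (1, 1, 1)))


class TestDiameters:
    def test_cylinder_diameter_matches_oracle(self):
        # axis through voxel centers (coordinate k + 0.5), so thinning finds
        # a true center voxel and the EDT there reads the full radius
        spec = sq.PhantomSpec(
            shape_vox=(24, 24, 40),
            voxel_size=(1, 1, 1),
            vessels=[sq.VesselTubeSpec(np.array([[12.5, 12.5, 0], [12.5, 12.5, 40]]), 5.0)],
        )
        _, truth = sq.make_vessel_phantom(spec)
        pts = sq.skeletonize(truth.mask)
        diameters, median = sq.diameters_along_skeleton(truth.mask, pts)
        assert median == pytest.approx(10.0, abs=1.0)
        # spot-check three points against the exhaustive nearest-background search
        for p in pts[:: max(1, len(pts) // 3)][:3]:
            r = brute_force_radius(truth.mask.mask, p, (1, 1, 1))
            d = diameters[np.flatnonzero((pts == p).all(axis=1))[0]]
            assert d == pytest.approx(2 * r, rel=1e-9)

    def test_single_voxel_reads_one_voxel_unit(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        _, median = sq.diameters_along_skeleton(
            sq.BinaryVolume(m, (1, 1, 1)), np.array([[2, 2, 2]])
        )
        assert median == pytest.approx(2.0)

    def test_diameters_scale_with_voxel_size(self):
        m = np.zeros((9, 9, 9), bool)
        m[3:6, 3:6, 3:6] = True
        pts = np.array([[4, 4, 4]])
        _, d1 = sq.diameters_along_skeleton(sq.BinaryVolume(m, (1, 1, 1)), pts)
        _, d2 = sq.diameters_along_skeleton(sq.BinaryVolume(m, (2, 2, 2)), pts)
        assert d2 == pytest.approx(2 * d1)

    def test_point_outside_mask_rejected(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        with pytest.raises(ValueError):
            sq.diameters_along_skeleton(sq.BinaryVolume(m, (1, 1, 1)), np.array([[0, 0, 0]]))


class TestDiffusionLength:
    def test_all_vessel_reads_zero(self):
        m = sq.BinaryVolume(np.ones((4, 4, 4), bool), (1, 1, 1))
        assert sq.diffusion_length(m) == 0.0

    def test_plane_source_matches_bruteforce_exactly(self):
        m = np.zeros((30, 6, 6), bool)
        m[0] = True  # vessel plane at z=0
        bv = sq.BinaryVolume(m, (1, 1, 1))
        assert sq.diffusion_length(bv) == sq.brute_force_rk(bv)
        # each distance 1..29 occurs once per column (36 columns)
        expected = np.quantile(np.repeat(np.arange(1, 30), 36), 0.9)
        assert sq.diffusion_length(bv) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sq.diffusion_length(sq.BinaryVolume(np.zeros((3, 3, 3), bool), (1, 1, 1)))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antitone_in_vessel_set(self, seed):
        rng = np.random.default_rng(seed)
        small = rng.random((10, 10, 10)) < 0.02
        if not small.any():
            small[5, 5, 5] = True
        extra = rng.random((10, 10, 10)) < 0.05
        big = small | extra
        vs = (3, 0.7, 0.7)
        rk_small = sq.diffusion_length(sq.BinaryVolume(small, vs))
        rk_big = sq.diffusion_length(sq.BinaryVolume(big, vs))
        assert rk_big <= rk_small + 1e-12
        vf_small = sq.volume_fraction(sq.BinaryVolume(small, vs))
        vf_big = sq.volume_fraction(sq.BinaryVolume(big, vs))
        assert vf_big >= vf_small


class TestRefineByIntensity:
    def test_refinement_restores_true_caliber(self, tube_phantom):
        _, (col4, truth) = tube_phantom
        v = sq.vesselness(col4, scales_um=[3, 5, 8])
        core = sq.segment_vessels(v, 0.05, 0.2, 20)
        refined = refine_by_intensity(col4, core)
        np.testing.assert_array_equal(refined.mask, truth.mask.mask)


class TestVascularMetrics:
    def test_identical_subvolumes_identity(self, tube_phantom):
        _, (col4, _) = tube_phantom
        net = sq.extract_network(col4, scales_um=[3, 5, 8])
        single = sq.vascular_metrics(net)
        double = sq.vascular_metrics([net, net])
        assert single.median_diameter_um == double.median_diameter_um
        assert single.vascular_vf == double.vascular_vf
        assert single.rk_um == double.rk_um
        assert double.n_subvolumes == 2

    def test_vf_mean_across_subvolumes(self):
        def net_with_vf(frac):
            m = np.zeros(1000, bool)
            m[: int(frac * 1000)] = True
            m = m.reshape(10, 10, 10)
            bv = sq.BinaryVolume(m, (1, 1, 1))
            pts = np.argwhere(m)[:1]
            return sq.VesselNetwork(bv, pts, np.array([1.0]), (1, 1, 1))

        res = sq.vascular_metrics([net_with_vf(0.02), net_with_vf(0.04)])
        assert res.vascular_vf == pytest.approx(0.03)

    def test_phantom_vf_recovered_through_pipeline(self, tube_phantom):
        _, (col4, truth) = tube_phantom
        net = sq.extract_network(col4, scales_um=[3, 5, 8])
        res = sq.vascular_metrics(net)
        assert abs(res.vascular_vf - truth.vessel_vf) / truth.vessel_vf < 0.1
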