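"""CSF-space morphometry: vessel subtraction, skeleton subdivision,
width mapping, regional statistics."""

import numpy as np
import pytest

from hydromorph import csf, imaging
from hydromorph.imaging import VoxelVolume


def slab_volume(thickness, n=24, pad=6):
    m = np.zeros((n, n, thickness + 2 * pad))
    m[2:-2, 2:-2, pad:pad + thickness] = 1
    return VoxelVolume(m)


class TestSubtractVessels:
    def test_empty_vessels_identity(self):
        m = VoxelVolume((np.random.default_rng(0).random((6, 6, 6)) > 0.5).astype(np.uint8))
        v = VoxelVolume(np.zeros((6, 6, 6), dtype=np.uint8))
        out = csf.subtract_vessels(m, v)
        assert np.array_equal(out.values, m.values)

    def test_superset_vessels_empty_output(self):
        m = VoxelVolume(np.ones((4, 4, 4), dtype=np.uint8))
        out = csf.subtract_vessels(m, m)
        assert out.values.sum() == 0

    def test_random_masks_match_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        b = (rng.random((5, 5, 5)) > 0.5).astype(np.uint8)
        out = csf.subtract_vessels(VoxelVolume(a), VoxelVolume(b))
        for idx in np.ndindex(a.shape):
            assert out.values[idx] == (a[idx] and not b[idx])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            csf.subtract_vessels(VoxelVolume(np.ones((4, 4, 4))),
                                 VoxelVolume(np.ones((5, 5, 5))))


class TestSubdivideSkeleton:
    def _sub(self, mask_vol, total_vol, thr=6.0):
        sk = imaging.skeletonize(mask_vol)
        outer = imaging.outer_surface_distance(total_vol)
        return sk, csf.subdivide_skeleton(sk, outer, thr)

    def test_shallow_shell_all_sas(self):
        # 3 mm slab at the top surface of a solid block: all depths <= 6
        total = np.zeros((20, 20, 20)); total[2:18, 2:18, 2:18] = 1
        m = np.zeros((20, 20, 20)); m[4:16, 4:16, 15:18] = 1
        _, (sas, sul) = self._sub(VoxelVolume(m), VoxelVolume(total))
        assert len(sul) == 0 and len(sas) > 0

    def test_buried_slab_all_sulcal(self):
        total = np.zeros((30, 30, 34)); total[2:28, 2:28, 2:32] = 1
        m = np.zeros((30, 30, 34)); m[10:20, 10:20, 14:17] = 1  # >10 mm deep
        _, (sas, sul) = self._sub(VoxelVolume(m), VoxelVolume(total))
        assert len(sas) == 0 and len(sul) > 0

    def test_partition_and_oracle_depths(self, default_masks):
        csf_mask, total = default_masks
        sk = imaging.skeletonize(csf_mask)
        outer = imaging.outer_surface_distance(total)
        sas, sul = csf.subdivide_skeleton(sk, outer)
        assert len(sas) + len(sul) == len(sk)
        # brute-force recomputation of each skeleton voxel's exterior depth
        bg = np.argwhere(total.values == 0)
        rng = np.random.default_rng(0)
        in_sas = sas.as_mask()
        for i in rng.choice(len(sk), size=40, replace=False):
            c = sk.coords[i]
            depth = np.sqrt(((bg - c) ** 2).sum(axis=1)).min()
            assert depth == pytest.approx(outer.values[tuple(c)])
            assert in_sas[tuple(c)] == (depth <= 6.0)

    def test_nonpositive_threshold_rejected(self, default_masks):
        csf_mask, total = default_masks
        sk = imaging.skeletonize(csf_mask)
        outer = imaging.outer_surface_distance(total)
        with pytest.raises(ValueError):
            csf.subdivide_skeleton(sk, outer, 0.0)


class TestWidthMap:
    def test_slab_calibration(self):
        # 5-voxel slab: medial EDT 3.0 -> width 2*3 - 0.5 = 5.5 (the
        # quarter-voxel-per-side calibration reads odd slabs high by half
        # a voxel and oblique sheets low by half a voxel)
        vol = slab_volume(5)
        sk = imaging.skeletonize(vol)
        w = csf.width_map(sk, imaging.edt(vol))
        medial = w.coords[:, 2] == 8
        assert np.median(w.width_mm[medial]) == pytest.approx(5.5)

    @pytest.mark.parametrize("t", range(3, 11))
    def test_slab_width_recovery_within_one_voxel(self, t):
        vol = slab_volume(t)
        sk = imaging.skeletonize(vol)
        w = csf.width_map(sk, imaging.edt(vol))
        interior = (np.abs(w.coords[:, 0] - 12) < 6) & (np.abs(w.coords[:, 1] - 12) < 6)
        assert abs(np.median(w.width_mm[interior]) - t) <= 1.0

    def test_spacing_doubling_doubles_widths(self):
        m = slab_volume(5).values
        v1, v2 = VoxelVolume(m, (1, 1, 1)), VoxelVolume(m, (2, 2, 2))
        w1 = csf.width_map(imaging.skeletonize(v1), imaging.edt(v1))
        w2 = csf.width_map(imaging.skeletonize(v2), imaging.edt(v2))
        assert np.allclose(sorted(w2.width_mm), 2 * np.asarray(sorted(w1.width_mm)))

    def test_zero_edt_rejected(self):
        vol = slab_volume(3)
        sk = imaging.skeletonize(vol)
        other = np.zeros(vol.shape); other[0, 0, 0] = 1
        bad_edt = imaging.edt(VoxelVolume(other))
        with pytest.raises(ValueError, match="zero"):
            csf.width_map(sk, bad_edt)


class TestRoiExtrude:
    def test_full_plane_all_slices(self):
        out = csf.roi_extrude(np.ones((5, 6)), 0, 4, (5, 6, 4))
        assert out.all()

    def test_single_pixel_column(self):
        roi = np.zeros((5, 6)); roi[2, 3] = 1
        out = csf.roi_extrude(roi, 1, 6, (5, 6, 8))
        assert out.sum() == 5
        assert out[2, 3, 1:6].all()

    def test_count_equals_pixels_times_slices(self):
        rng = np.random.default_rng(0)
        roi = rng.random((7, 7)) > 0.6
        roi[0, 0] = True
        out = csf.roi_extrude(roi, 2, 9, (7, 7, 12))
        assert out.sum() == roi.sum() * 7

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            csf.roi_extrude(np.zeros((4, 4)), 0, 2, (4, 4, 4))


class TestRegionWidthStats:
    def _skeleton_with_widths(self, widths):
        coords = np.array([[i, 0, 0] for i in range(len(widths))])
        sk = imaging.Skeleton(coords, (1, 1, 1), (len(widths), 3, 3))
        sk.width_mm = np.asarray(widths, dtype=float)
        return sk

    def test_constant_widths(self):
        sk = self._skeleton_with_widths([4.0, 4.0, 4.0])
        st = csf.region_width_stats(sk, np.ones((3, 3, 3)), "r")
        assert st.mean_width_mm == st.max_width_mm == 4.0

    def test_arithmetic(self):
        sk = self._skeleton_with_widths([2.0, 4.0, 6.0])
        st = csf.region_width_stats(sk, np.ones((3, 3, 3)), "r")
        assert st.mean_width_mm == pytest.approx(4.0)
        assert st.max_width_mm == pytest.approx(6.0)

    def test_empty_intersection_explicit(self):
        sk = self._skeleton_with_widths([2.0, 4.0])
        st = csf.region_width_stats(sk, np.zeros((2, 3, 3)), "r")
        assert st.n_skeleton_voxels == 0
        assert np.isnan(st.mean_width_mm)

    def test_phantom_regional_recovery(self, default_phantom, default_masks):
        # frontal shell 5 mm / IHF slab 3 mm recovered within +-1 mm
        spec, _, _, truth = default_phantom
        csf_mask, total = default_masks
        sk = imaging.skeletonize(csf_mask)
        outer = imaging.outer_surface_distance(total)
        csf.subdivide_skeleton(sk, outer)
        w = csf.width_map(sk, imaging.edt(csf_mask))
        fs = csf.region_width_stats(w, truth.roi_frontal, "frontal")
        ih = csf.region_width_stats(w, truth.roi_ihf, "ihf")
        assert abs(fs.mean_width_mm - 5.0) <= 1.0
        assert abs(ih.mean_width_mm - 3.0) <= 1.0

    def test_vessel_subtraction_never_increases_widths(self, default_phantom, default_masks):
        _, _, labels, truth = default_phantom
        csf_mask, total = default_masks
        vessels = VoxelVolume((labels.values == 10).astype(np.uint8))
        adj = csf.subtract_vessels(csf_mask, vessels)

        def stats_for(mask):
            sk = imaging.skeletonize(mask)
            w = csf.width_map(sk, imaging.edt(mask))
            return csf.region_width_stats(w, truth.roi_frontal, "f")

        before, after = stats_for(csf_mask), stats_for(adj)
        assert after.max_width_mm <= before.max_width_mm + 1e-9
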