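"""Morphological primitives: largest component, lobe merging, metric erosion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from ldctqa.mask_ops import (
    EmptyMaskError,
    erode_inplane_margin,
    largest_component,
    merge_lobes,
)
from ldctqa.segmentation import LOBE_LABELS, BinaryMask3D


def mask_of(voxels, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask3D(np.asarray(voxels, dtype=bool), spacing)


def random_mask(seed, shape=(12, 12, 8), density=0.3, spacing=(1.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    return mask_of(rng.random(shape) < density, spacing)


class TestLargestComponent:
    def test_keeps_larger_of_two_blobs(self):
        vox = np.zeros((20, 10, 10), dtype=bool)
        vox[1:6, 1:6, 1:5] = True   # 100 voxels
        vox[15:16, 1:6, 1:2] = True  # 5 voxels
        out = largest_component(mask_of(vox))
        assert out.n_voxels == 100
        assert not out.voxels[15:, :, :].any()

    def test_single_blob_is_identity(self):
        vox = np.zeros((8, 8, 8), dtype=bool)
        vox[2:6, 2:6, 2:6] = True
        out = largest_component(mask_of(vox))
        np.testing.assert_array_equal(out.voxels, vox)

    def test_equal_blobs_tie_break_smallest_linear_index(self):
        # two 50-voxel blobs; brute-force check that the winner is the
        # component containing the globally smallest flat index
        vox = np.zeros((20, 5, 5), dtype=bool)
        vox[1:3, 0:5, 0:5] = True
        vox[10:12, 0:5, 0:5] = True
        out = largest_component(mask_of(vox))
        labels, n = ndi.label(vox, structure=ndi.generate_binary_structure(3, 3))
        assert n == 2
        first_label = labels.ravel()[np.argmax(labels.ravel() > 0)]
        np.testing.assert_array_equal(out.voxels, labels == first_label)
        assert out.voxels[1, 0, 0] and not out.voxels[10, 0, 0]

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EmptyMaskError):
            largest_component(mask_of(np.zeros((4, 4, 4))))

    def test_connectivity_6_splits_diagonal_bridge(self):
        vox = np.zeros((6, 6, 2), dtype=bool)
        vox[0:2, 0:2, 0] = True
        vox[2, 2, 0] = True  # diagonal neighbour only
        assert largest_component(mask_of(vox), connectivity=26).n_voxels == 5
        assert largest_component(mask_of(vox), connectivity=6).n_voxels == 4

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        m = random_mask(seed)
        if m.n_voxels == 0:
            return
        once = largest_component(m)
        twice = largest_component(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)


class TestMergeLobes:
    def _disjoint_lobes(self):
        lobes = {}
        for i, label in enumerate(LOBE_LABELS):
            vox = np.zeros((30, 6, 6), dtype=bool)
            vox[6 * i:6 * i + 3, 1:4, 1:4] = True
            lobes[label] = mask_of(vox)
        return lobes

    def test_union_of_disjoint_lobes(self):
        lobes = self._disjoint_lobes()
        merged = merge_lobes(lobes)
        expected = np.zeros((30, 6, 6), dtype=bool)
        for m in lobes.values():
            expected |= m.voxels
        np.testing.assert_array_equal(merged.voxels, expected)

    def test_single_voxel_satellite_removed(self):
        lobes = self._disjoint_lobes()
        vox = lobes["right_upper"].voxels.copy()
        vox[29, 5, 5] = True  # isolated voxel far from the blob
        lobes["right_upper"] = mask_of(vox)
        merged = merge_lobes(lobes)
        assert not merged.voxels[29, 5, 5]

    def test_overlapping_lobes_union_is_boolean(self):
        lobes = self._disjoint_lobes()
        lobes["right_middle"] = lobes["right_upper"].copy()
        merged = merge_lobes(lobes)
        assert merged.voxels.dtype == bool
        assert merged.n_voxels == 4 * 27  # overlap not double-counted

    def test_one_empty_lobe_warns_but_merges(self):
        lobes = self._disjoint_lobes()
        lobes["left_lower"] = mask_of(np.zeros((30, 6, 6)))
        with pytest.warns(UserWarning, match="left_lower"):
            merged = merge_lobes(lobes)
        assert merged.n_voxels == 4 * 27

    def test_all_empty_is_an_error(self):
        lobes = {l: mask_of(np.zeros((6, 6, 6))) for l in LOBE_LABELS}
        with pytest.warns(UserWarning), pytest.raises(EmptyMaskError):
            merge_lobes(lobes)


class TestErodeInplaneMargin:
    def test_zero_margin_is_identity(self):
        m = random_mask(3)
        out = erode_inplane_margin(m, 0.0)
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_metric_margin_holds_by_distance_transform(self):
        # disk of radius 10 voxels at 1 mm spacing, margin 3 mm
        xx, yy = np.meshgrid(np.arange(25) - 12, np.arange(25) - 12, indexing="ij")
        disk = (xx ** 2 + yy ** 2 <= 100)[:, :, None]
        m = mask_of(disk)
        out = erode_inplane_margin(m, 3.0)
        assert out.n_voxels > 0
        dist = ndi.distance_transform_edt(disk[:, :, 0], sampling=(1.0, 1.0))
        assert np.all(dist[out.voxels[:, :, 0]] >= 3.0)

    def test_margin_respects_anisotropic_inplane_spacing(self):
        xx, yy = np.meshgrid(np.arange(41) - 20, np.arange(21) - 10, indexing="ij")
        disk = ((0.5 * xx) ** 2 + (1.0 * yy) ** 2 <= 64)[:, :, None]  # 8 mm radius
        m = mask_of(disk, spacing=(0.5, 1.0, 2.0))
        out = erode_inplane_margin(m, 3.0)
        assert out.n_voxels > 0
        dist = ndi.distance_transform_edt(disk[:, :, 0], sampling=(0.5, 1.0))
        assert np.all(dist[out.voxels[:, :, 0]] >= 3.0)

    def test_ribbon_thinner_than_margin_vanishes(self):
        vox = np.zeros((20, 20, 3), dtype=bool)
        vox[:, 8:11, :] = True  # 3 voxels wide at 1 mm
        assert erode_inplane_margin(mask_of(vox), 3.0).n_voxels == 0

    def test_no_z_coupling(self):
        # a one-slice plate must erode exactly like the same plate stacked
        plate = np.zeros((15, 15, 1), dtype=bool)
        plate[2:13, 2:13, 0] = True
        stacked = np.repeat(plate, 5, axis=2)
        out1 = erode_inplane_margin(mask_of(plate), 2.0)
        out5 = erode_inplane_margin(mask_of(stacked), 2.0)
        for k in range(5):
            np.testing.assert_array_equal(out5.voxels[:, :, k], out1.voxels[:, :, 0])

    @given(st.integers(0, 500), st.floats(0.0, 4.0), st.floats(0.0, 4.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_output_subset_and_monotone_in_margin(self, seed, m1, m2):
        mask = random_mask(seed, density=0.6)
        lo, hi = sorted((m1, m2))
        out_lo = erode_inplane_margin(mask, lo)
        out_hi = erode_inplane_margin(mask, hi)
        assert np.all(out_lo.voxels <= mask.voxels)
        assert np.all(out_hi.voxels <= out_lo.voxels)
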