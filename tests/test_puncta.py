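"""Segmentation and puncta properties against oracles and arithmetic checks."""

import numpy as np
import pytest

import synaptoquant as sq
from synaptoquant import puncta
from conftest import flood_fill_26, match_puncta, partitions_equal


def gaussian_blob(shape, center, sigma, amp=100.0):
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, np.broadcast_to(sigma, (len(shape),))))
    return amp * np.exp(-0.5 * d2)


class TestLabel26:
    def test_corner_touching_voxels_are_one_component(self):
        vol = np.zeros((3, 3, 3), dtype=bool)
        vol[0, 0, 0] = vol[1, 1, 1] = True
        assert puncta.label_components_26(vol).n_puncta == 1

    def test_axis_gap_of_one_makes_two_components(self):
        vol = np.zeros((1, 1, 3), dtype=bool)
        vol[0, 0, 0] = vol[0, 0, 2] = True
        assert puncta.label_components_26(vol).n_puncta == 2

    def test_matches_flood_fill_oracle_on_random_volumes(self, rng):
        for _ in range(25):
            vol = rng.random((10, 10, 10)) < 0.3
            ours = puncta.label_components_26(vol)
            oracle, n = flood_fill_26(vol)
            assert ours.n_puncta == n
            assert partitions_equal(ours.labels, oracle)


class TestSegment3D:
    def test_well_separated_puncta_found(self):
        vol = gaussian_blob((9, 31, 61), (4, 15, 15), 2.0) + gaussian_blob(
            (9, 31, 61), (4, 15, 45), 2.0
        )
        lab = puncta.segment_puncta_3d(vol, 20.0, sharpen_first=False)
        assert lab.n_puncta == 2

    def test_watershed_splits_fused_pair_at_saddle(self):
        # two peaks 3 sigma apart: one threshold component with a saddle
        vol = gaussian_blob((7, 31, 41), (3, 15, 17), 2.0) + gaussian_blob(
            (7, 31, 41), (3, 15, 23), 2.0
        )
        on = puncta.segment_puncta_3d(vol, 20.0, sharpen_first=False, watershed=True)
        off = puncta.segment_puncta_3d(vol, 20.0, sharpen_first=False, watershed=False)
        assert off.n_puncta == 1
        assert on.n_puncta == 2

    def test_watershed_split_conserves_voxel_partition(self):
        vol = gaussian_blob((7, 31, 41), (3, 15, 17), 2.0) + gaussian_blob(
            (7, 31, 41), (3, 15, 23), 2.0
        )
        on = puncta.segment_puncta_3d(vol, 20.0, sharpen_first=False, watershed=True)
        off = puncta.segment_puncta_3d(vol, 20.0, sharpen_first=False, watershed=False)
        assert (on.labels > 0).sum() == (off.labels > 0).sum()
        assert np.array_equal(on.labels > 0, off.labels > 0)

    def test_empty_volume_yields_zero_puncta_not_error(self):
        lab = puncta.segment_puncta_3d(np.zeros((4, 8, 8)), 10.0)
        assert lab.n_puncta == 0

    def test_raising_threshold_never_increases_labeled_voxels(self):
        vol = gaussian_blob((7, 21, 21), (3, 10, 10), 2.5)
        counts = [
            (puncta.segment_puncta_3d(vol, thr, sharpen_first=False).labels > 0).sum()
            for thr in (5.0, 10.0, 20.0, 40.0, 80.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recovery_on_synthetic_stack_at_high_snr(self):
        stack, (gt_a, _) = sq.gen_dendrite_stack(
            length_um=60, n_puncta=(60, 60), coincidence=0.5, noise_sd=10.0, seed=11
        )
        chan = stack.voxels[0]
        lab = puncta.segment_puncta_3d(chan, puncta.robust_threshold(chan))
        pset = puncta.puncta_properties(lab, chan, stack.voxel_size)
        tp = match_puncta(pset, gt_a)
        assert tp / len(gt_a) >= 0.9
        assert tp / len(pset) >= 0.9


class TestProperties:
    def test_intensity_arithmetic(self):
        labels = puncta.LabelMap(labels=np.array([[[1, 1, 1, 0]]]), n_puncta=1)
        raw = np.array([[[10.0, 20.0, 30.0, 99.0]]])
        pset = puncta.puncta_properties(labels, raw, (0.3, 0.1, 0.1))
        p = pset.puncta[0]
        assert p.integrated_intensity == 60.0
        assert p.mean_intensity == 20.0
        assert p.integrated_intensity == p.mean_intensity * p.voxel_count

    def test_volume_is_voxel_count_times_voxel_volume(self):
        grid = np.zeros((2, 3, 3), dtype=int)
        grid[0, 0, :2] = 1
        grid[1, 1, :3] = 1
        pset = puncta.puncta_properties(
            puncta.LabelMap(labels=grid, n_puncta=1), np.ones_like(grid, dtype=float),
            (0.3, 0.1, 0.1),
        )
        assert pset.puncta[0].volume_um3 == pytest.approx(5 * 0.003)

    def test_centroid_matches_generator_center_within_half_voxel(self):
        stack, (gt_a, _) = sq.gen_dendrite_stack(
            n_puncta=(6, 6), coincidence=0.0, noise_sd=0.0, seed=9
        )
        chan = stack.voxels[0]
        lab = puncta.segment_puncta_3d(chan, 10.0, sharpen_first=False)
        pset = puncta.puncta_properties(lab, chan, stack.voxel_size)
        assert len(pset) == 6
        half_voxel = np.linalg.norm(np.asarray(stack.voxel_size)) / 2
        for p in pset.puncta:
            d = np.linalg.norm(gt_a.centers_um - np.asarray(p.centroid_um), axis=1)
            assert d.min() <= half_voxel

    def test_voxel_counts_cover_all_labeled_voxels(self, rng):
        vol = rng.random((6, 12, 12)) < 0.2
        lab = puncta.label_components_26(vol)
        pset = puncta.puncta_properties(lab, rng.random(vol.shape), (0.3, 0.1, 0.1))
        assert sum(p.voxel_count for p in pset.puncta) == int(vol.sum())

    def test_missing_voxel_size_is_error(self):
        lab = puncta.LabelMap(labels=np.ones((1, 2, 2), dtype=int), n_puncta=1)
        with pytest.raises(ValueError, match="voxel_size"):
            puncta.puncta_properties(lab, np.ones((1, 2, 2)), None)

    def test_density_reported_per_100um(self):
        pset = puncta.PunctaSet(
            puncta=[None] * 12, dendrite_length_um=60.0  # only count matters
        )
        assert pset.density_per_100um() == pytest.approx(20.0)


class TestDetect2D:
    def test_cluster_below_min_pixels_discarded(self):
        img = np.zeros((10, 10))
        img[2, 2:5] = 100.0  # 3-pixel cluster
        pset, _ = puncta.detect_puncta_2d(img, 50.0, min_pixels=4)
        assert pset.count == 0

    def test_four_pixel_cluster_counts(self):
        img = np.zeros((10, 10))
        img[2, 2:6] = 100.0
        pset, _ = puncta.detect_puncta_2d(img, 50.0, min_pixels=4)
        assert pset.count == 1

    def test_k_disjoint_clusters_count_k(self):
        img = np.zeros((12, 40))
        k = 5
        for i in range(k):
            img[4:5, 2 + 7 * i : 7 + 7 * i] = 100.0
        pset, _ = puncta.detect_puncta_2d(img, 50.0)
        assert pset.count == k


class TestSelectSynaptic:
    @staticmethod
    def _scene():
        img = np.zeros((40, 60))
        part = np.zeros_like(img)
        mask = np.zeros_like(img, dtype=bool)
        mask[18:22, :] = True
        return img, part, mask

    def test_punctum_just_beyond_max_dist_excluded(self):
        img, part, mask = self._scene()
        img[27:29, 10:12] = 100.0  # 5 px from mask edge (rows 22..26 gap)
        part[27:29, 10:12] = 100.0
        _, lab = puncta.detect_puncta_2d(img, 50.0)
        kept, _ = puncta.select_synaptic_puncta(lab, img, part, mask, (10.0, 10.0), 4.0)
        assert kept.count == 0

    def test_on_mask_above_background_retained(self):
        img, part, mask = self._scene()
        img[19:21, 10:12] = 100.0
        part[19:21, 10:12] = 80.0
        _, lab = puncta.detect_puncta_2d(img, 50.0)
        kept, _ = puncta.select_synaptic_puncta(lab, img, part, mask, (10.0, 10.0), 4.0)
        assert kept.count == 1

    def test_dim_partner_channel_excludes(self):
        img, part, mask = self._scene()
        img[19:21, 10:12] = 100.0
        part[19:21, 10:12] = 5.0  # below partner background
        _, lab = puncta.detect_puncta_2d(img, 50.0)
        kept, _ = puncta.select_synaptic_puncta(lab, img, part, mask, (10.0, 10.0), 4.0)
        assert kept.count == 0

    def test_programmed_off_dendrite_fraction_recovered(self, rng):
        img, part, mask = self._scene()
        img = np.zeros((60, 200))
        part = np.zeros_like(img)
        mask = np.zeros_like(img, dtype=bool)
        mask[28:33, :] = True
        n, on = 40, 28  # 30% programmed off-dendrite
        xs = rng.choice(np.arange(5, 195, 4), size=n, replace=False)
        for k, x in enumerate(xs):
            y = 30 if k < on else 50
            img[y - 1 : y + 1, x - 1 : x + 1] = 100.0
            part[y - 1 : y + 1, x - 1 : x + 1] = 80.0
        _, lab = puncta.detect_puncta_2d(img, 50.0)
        kept, _ = puncta.select_synaptic_puncta(lab, img, part, mask, (10.0, 10.0), 4.0)
        assert kept.count == on
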