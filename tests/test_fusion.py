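"""Station fusion, connected components (vs a brute-force oracle), volumetry."""

from collections import deque

import numpy as np
import pytest

from kidneyvol.fusion import FusedSubject, connected_components, fuse_stations, measure
from kidneyvol.image import LabelVolume, VolumeImage
from kidneyvol.phantom import PhantomConfig, generate_subject


def bfs_flood_fill(mask):
    """Independent 6-connectivity component labelling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    comps = []
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        comp = np.zeros_like(mask)
        q = deque([start])
        visited[start] = True
        while q:
            p = q.popleft()
            comp[p] = True
            for d in offsets:
                nb = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)) and mask[nb] and not visited[nb]:
                    visited[nb] = True
                    q.append(nb)
        comps.append(comp)
    return comps


def _stations_from_subject(s):
    return s.station_a["water"], s.station_b["water"], s.truth_a, s.truth_b


class TestFuseStations:
    def test_identical_overlap_content_unchanged(self):
        cfg = PhantomConfig.desk_scale(seed=2, noise_sd=0.0)
        s = generate_subject(cfg)
        fused = fuse_stations(*_stations_from_subject(s))
        ov = slice(*fused.overlap_range)
        np.testing.assert_allclose(
            fused.fused_water.data[:, :, ov],
            s.station_a["water"].data[:, :, fused.overlap_range[0]:],
            atol=1e-6,
        )
        assert fused.overlap_range == (16, 16 + 8) or fused.overlap_range == (8, 16)

    def test_blend_weights_sum_to_one(self, rng):
        a = VolumeImage(np.full((4, 4, 10), 2.0, dtype=np.float32), (1, 1, 1))
        b = VolumeImage(np.full((4, 4, 10), 6.0, dtype=np.float32), (1, 1, 1), (0, 0, 6.0))
        la = LabelVolume(np.zeros((4, 4, 10)), (1, 1, 1))
        lb = LabelVolume(np.zeros((4, 4, 10)), (1, 1, 1), (0, 0, 6.0))
        fused = fuse_stations(a, b, la, lb)
        ov = fused.fused_water.data[:, :, slice(*fused.overlap_range)]
        # convex blend of constants 2 and 6 stays within, increasing toward b
        assert (ov >= 2.0 - 1e-6).all() and (ov <= 6.0 + 1e-6).all()
        profile = ov[0, 0, :]
        assert (np.diff(profile) > 0).all()

    def test_half_weight_disagreement_thresholds_to_kidney(self):
        # one overlap slice at ramp weight 1/2: labels 1 and 0 blend to 0.5 -> label 1
        a = VolumeImage(np.zeros((2, 2, 3), dtype=np.float32), (1, 1, 1))
        b = VolumeImage(np.zeros((2, 2, 3), dtype=np.float32), (1, 1, 1), (0, 0, 2.0))
        la = LabelVolume(np.ones((2, 2, 3)), (1, 1, 1))
        lb = LabelVolume(np.zeros((2, 2, 3)), (1, 1, 1), (0, 0, 2.0))
        fused = fuse_stations(a, b, la, lb)
        assert fused.overlap_range == (2, 3)
        assert fused.fused_probabilities.data[0, 0, 2] == pytest.approx(0.5)
        assert fused.fused_labels.data[0, 0, 2] == 1

    def test_zero_motion_truth_recovers_whole_volume(self):
        cfg = PhantomConfig.desk_scale(seed=2, noise_sd=0.0)
        s = generate_subject(cfg)
        fused = fuse_stations(*_stations_from_subject(s))
        ref = s.truth_fused.as_bool().sum()
        got = fused.fused_labels.as_bool().sum()
        assert got == ref  # identical sources: blend is exact

    def test_incompatible_spacing_rejected(self):
        a = VolumeImage(np.zeros((4, 4, 4)), (1, 1, 1))
        b = VolumeImage(np.zeros((4, 4, 4)), (1, 1, 2), (0, 0, 2))
        l = LabelVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="spacing"):
            fuse_stations(a, b, l, l)

    def test_zero_overlap_concatenates_with_warning(self):
        a = VolumeImage(np.ones((3, 3, 4)), (1, 1, 1))
        b = VolumeImage(np.full((3, 3, 4), 2.0), (1, 1, 1), (0, 0, 4.0))
        la = LabelVolume(np.zeros((3, 3, 4)), (1, 1, 1))
        lb = LabelVolume(np.zeros((3, 3, 4)), (1, 1, 1), (0, 0, 4.0))
        with pytest.warns(UserWarning, match="overlap"):
            fused = fuse_stations(a, b, la, lb)
        assert fused.fused_water.shape[2] == 8


class TestConnectedComponents:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:3, :3, :3] = True
        mask[6:9, 6:9, 6:9] = True
        comps = connected_components(mask)
        assert len(comps) == 2
        assert all(c.sum() == 27 for c in comps)

    def test_sizes_sorted_descending_with_scrap(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[0:4, 0:5, 0:5] = True    # 100
        mask[6:10, 0:4, 0:5] = True   # 80
        mask[11, 7:12, 5] = True      # 5
        comps = connected_components(mask)
        assert [int(c.sum()) for c in comps] == [100, 80, 5]

    def test_diagonal_touch_is_separate_under_face_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        assert len(connected_components(mask, connectivity=6)) == 2
        assert len(connected_components(mask, connectivity=26)) == 1

    def test_empty_mask_gives_empty_list(self):
        assert connected_components(np.zeros((3, 3, 3), dtype=bool)) == []

    def test_matches_bfs_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            mask = rng.random((12, 12, 12)) < 0.25
            ours = connected_components(mask)
            oracle = bfs_flood_fill(mask)
            assert len(ours) == len(oracle)
            assert sum(c.sum() for c in ours) == mask.sum()
            ours_sorted = sorted((tuple(map(tuple, np.argwhere(c)[:1])), int(c.sum())) for c in ours)
            oracle_sorted = sorted((tuple(map(tuple, np.argwhere(c)[:1])), int(c.sum())) for c in oracle)
            assert ours_sorted == oracle_sorted


class TestMeasure:
    def _fused_from_mask(self, mask, spacing=(1, 1, 1)):
        lv = LabelVolume(mask.astype(np.uint8), spacing)
        water = VolumeImage(np.zeros(mask.shape, dtype=np.float32), spacing)
        return FusedSubject(water, lv, LabelVolume(mask.astype(np.float32), spacing), (0, 0))

    def test_two_equal_components_at_station_spacing(self):
        mask = np.zeros((20, 30, 20), dtype=bool)
        mask[5:15, 2:12, 5:15] = True    # 1000 voxels, right (low column)
        mask[5:15, 18:28, 5:15] = True   # 1000 voxels, left
        m = measure(self._fused_from_mask(mask, (2.232, 2.232, 4.5)))
        assert m.left_volume_cm3 == pytest.approx(22.418208)
        assert m.right_volume_cm3 == pytest.approx(22.418208)
        assert m.combined_volume_cm3 == pytest.approx(44.836416)
        assert m.scrap_fraction == 0.0
        assert m.n_components == 2

    def test_three_four_five_distance(self):
        mask = np.zeros((40, 50, 3), dtype=bool)
        mask[0, 0, 0] = True
        mask[30, 40, 0] = True
        m = measure(self._fused_from_mask(mask))
        assert m.distance_mm == pytest.approx(50.0)
        assert m.relative_offset_mm[2] == pytest.approx(0.0)

    def test_scrap_fraction_from_three_components(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[0:4, 0:5, 0:5] = True
        mask[6:10, 7:11, 0:5] = True
        mask[11, 0:5, 11] = True
        m = measure(self._fused_from_mask(mask))
        assert m.scrap_fraction == pytest.approx(5 / 185)
        assert m.n_components == 3

    def test_left_right_identified_by_column_com(self):
        mask = np.zeros((10, 30, 10), dtype=bool)
        mask[2:5, 20:25, 2:5] = True  # higher column -> subject's left
        mask[2:8, 2:7, 2:8] = True    # bigger, lower column -> right
        m = measure(self._fused_from_mask(mask))
        assert m.right_volume_cm3 > m.left_volume_cm3
        assert m.left_com_mm[1] > m.right_com_mm[1]

    def test_single_component_reports_unilateral(self):
        mask = np.zeros((10, 30, 10), dtype=bool)
        mask[2:5, 22:27, 2:5] = True
        m = measure(self._fused_from_mask(mask))
        assert m.right_volume_cm3 == 0.0
        assert m.left_volume_cm3 > 0
        assert m.distance_mm is None and m.right_com_mm is None

    def test_empty_mask_flagged_as_zero(self):
        m = measure(self._fused_from_mask(np.zeros((5, 5, 5), dtype=bool)))
        assert m.combined_volume_cm3 == 0.0 and m.n_components == 0

    def test_component_conservation(self, rng):
        mask = rng.random((15, 15, 15)) < 0.2
        comps = connected_components(mask)
        m = measure(self._fused_from_mask(mask))
        total = int(mask.sum())
        kept = sum(int(c.sum()) for c in comps[:2])
        assert m.scrap_fraction == pytest.approx((total - kept) / total)
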