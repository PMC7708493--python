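"""Quality cost terms and two-stage percentile flagging."""

import numpy as np
import pandas as pd
import pytest

from kidneyvol.image import LabelVolume, VolumeImage
from kidneyvol.phantom import PhantomConfig, generate_subject
from kidneyvol.preprocess import normalize_station
from kidneyvol.qc import (
    flag_outliers,
    image_fusion_cost,
    location_cost,
    scrap_cost,
    segmentation_fusion_cost,
    smoothness_cost,
)


def _pair(data_a, data_b, zb):
    a = VolumeImage(np.asarray(data_a, dtype=np.float32), (1, 1, 1))
    b = VolumeImage(np.asarray(data_b, dtype=np.float32), (1, 1, 1), (0, 0, float(zb)))
    return a, b


class TestImageFusionCost:
    def test_identical_overlap_is_zero(self, rng):
        d = rng.random((4, 4, 6)).astype(np.float32)
        a, b = _pair(d, d[:, :, 2:], 2)
        b = VolumeImage(np.concatenate([d[:, :, 2:], d[:, :, :2]], axis=2), (1, 1, 1), (0, 0, 2))
        a = VolumeImage(d, (1, 1, 1))
        assert image_fusion_cost(a, b) == pytest.approx(0.0)

    def test_maximal_disagreement_is_one(self):
        a, b = _pair(np.zeros((3, 3, 4)), np.ones((3, 3, 4)), 2)
        assert image_fusion_cost(a, b) == pytest.approx(1.0)

    def test_empty_overlap_rejected(self):
        a, b = _pair(np.zeros((3, 3, 2)), np.zeros((3, 3, 2)), 5)
        with pytest.raises(ValueError, match="overlap"):
            image_fusion_cost(a, b)

    def test_injected_shift_increases_cost(self):
        costs = []
        for si in (0.0, 9.0):
            cfg = PhantomConfig.desk_scale(seed=5, motion_offset_mm=(0, 0, si))
            s = generate_subject(cfg)
            costs.append(
                image_fusion_cost(
                    normalize_station(s.station_a["water"]),
                    normalize_station(s.station_b["water"]),
                )
            )
        assert costs[1] > costs[0]


class TestSegmentationFusionCost:
    def _labels(self, ma, mb, zb):
        la = LabelVolume(np.asarray(ma, dtype=np.uint8), (1, 1, 1))
        lb = LabelVolume(np.asarray(mb, dtype=np.uint8), (1, 1, 1), (0, 0, float(zb)))
        return la, lb

    def test_identical_masks_cost_zero(self, rng):
        m = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        la, lb = self._labels(m, m, 0)
        assert segmentation_fusion_cost(la, lb) == 0.0

    def test_disjoint_masks_cost_one(self):
        ma = np.zeros((4, 4, 4)); ma[0, 0, :] = 1
        mb = np.zeros((4, 4, 4)); mb[3, 3, :] = 1
        la, lb = self._labels(ma, mb, 0)
        assert segmentation_fusion_cost(la, lb) == 1.0

    def test_hand_counted_dice(self):
        # |A|=4, |B|=6, |A∩B|=3 -> 1 - 2*3/10 = 0.4
        ma = np.zeros((4, 4, 1)); ma.ravel()[:4] = 1
        mb = np.zeros((4, 4, 1)); mb.ravel()[1:7] = 1
        la, lb = self._labels(ma, mb, 0)
        assert segmentation_fusion_cost(la, lb) == pytest.approx(0.4)

    def test_both_empty_is_zero(self):
        la, lb = self._labels(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)), 0)
        assert segmentation_fusion_cost(la, lb) == 0.0


class TestLocationCost:
    def _mask_at(self, z0, z1, nz=20):
        m = np.zeros((4, 4, nz), dtype=np.uint8)
        m[1:3, 1:3, z0:z1] = 1
        return LabelVolume(m, (1, 1, 1))

    def test_centred_mask_is_zero(self):
        assert location_cost(self._mask_at(9, 11)) == pytest.approx(0.0, abs=0.03)

    def test_edge_mask_near_one(self):
        assert location_cost(self._mask_at(0, 1)) == pytest.approx(0.95, abs=0.05)

    def test_quarter_offset_is_half(self):
        # COM at z=4.5 in a 20-slice volume: |4.5-9.5|/10 = 0.5
        assert location_cost(self._mask_at(4, 6)) == pytest.approx(0.5)

    def test_empty_mask_rates_worst(self):
        assert location_cost(LabelVolume(np.zeros((4, 4, 8)), (1, 1, 1))) == 1.0


class TestSmoothnessCost:
    def _from_areas(self, areas):
        nz = len(areas)
        m = np.zeros((20, 20, nz), dtype=np.uint8)
        for z, a in enumerate(areas):
            m.ravel()[z + np.arange(a) * nz] = 1  # a voxels in slice z
        lv = LabelVolume(np.transpose(m, (0, 1, 2)), (1, 1, 1))
        assert list(lv.as_bool().sum(axis=(0, 1))) == list(areas)
        return lv

    def test_constant_profile_costs_zero(self):
        assert smoothness_cost(self._from_areas([50, 50, 50, 50])) == 0.0

    def test_oscillating_profile_worse_than_smooth(self):
        rough = smoothness_cost(self._from_areas([0, 100, 0, 100, 0]))
        smooth = smoothness_cost(self._from_areas([80, 100, 100, 80]))
        assert rough > smooth
        # direct evaluation: active range (1..3), diffs |100-0|,|0-100| -> wait,
        # rough active range is slices 1..3: areas (100, 0, 100),
        # mean |diff| = 100, mean area = 200/3 -> cost 1.5
        assert rough == pytest.approx(1.5)
        assert smooth == pytest.approx((20 + 0 + 20) / 3 / 90)

    def test_disconnected_island_increases_cost(self, desk_subject):
        clean = desk_subject.truth_fused
        cost_clean = smoothness_cost(clean)
        lab = clean.data.astype(np.uint8).copy()
        lab[4:8, 4:8, 11:13] = 1  # island mid-stack, away from kidneys
        cost_island = smoothness_cost(LabelVolume(lab, clean.spacing_mm))
        assert cost_island > cost_clean

    def test_single_slice_mask_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            assert smoothness_cost(self._from_areas([0, 7, 0])) == 0.0


class TestScrapCost:
    def test_three_components_counts_smallest(self):
        m = np.zeros((12, 12, 12), dtype=np.uint8)
        m[0:4, 0:5, 0:5] = 1
        m[6:10, 7:11, 0:5] = 1
        m[11, 0:5, 11] = 1
        assert scrap_cost(LabelVolume(m, (1, 1, 1))) == pytest.approx(5 / 185)

    def test_two_components_is_zero(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[0:2, 0:2, 0:2] = 1
        m[5:7, 5:7, 5:7] = 1
        assert scrap_cost(LabelVolume(m, (1, 1, 1))) == 0.0

    def test_three_equal_components(self):
        m = np.zeros((12, 12, 3), dtype=np.uint8)
        for i, r in enumerate((0, 4, 8)):
            m[r : r + 1, 0:10, 1] = 1  # 10 voxels each
        assert scrap_cost(LabelVolume(m, (1, 1, 1))) == pytest.approx(10 / 30)

    def test_matches_measure_scrap_fraction(self, desk_subject):
        from kidneyvol.fusion import FusedSubject, measure

        lab = desk_subject.truth_fused.data.astype(np.uint8).copy()
        lab[0:2, 0:2, 0:2] = 1
        lv = LabelVolume(lab, desk_subject.truth_fused.spacing_mm)
        water = VolumeImage(np.zeros(lv.shape, dtype=np.float32), lv.spacing_mm)
        fused = FusedSubject(water, lv, lv, (0, 0))
        assert scrap_cost(lv) == pytest.approx(measure(fused).scrap_fraction)


class TestFlagOutliers:
    def _table(self, n, rng, **spikes):
        cols = ["image_fusion_cost", "segmentation_fusion_cost", "location_cost",
                "smoothness_cost", "scrap_cost"]
        df = pd.DataFrame({c: rng.random(n) * 0.1 for c in cols})
        df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
        for col, idxs in spikes.items():
            df.loc[idxs, col] = 5.0
        return df

    def test_identical_costs_flag_nobody(self):
        df = pd.DataFrame(
            {c: [0.3] * 20 for c in
             ["image_fusion_cost", "segmentation_fusion_cost", "location_cost",
              "smoothness_cost", "scrap_cost"]}
        )
        out, summary = flag_outliers(df)
        assert summary["excluded"] == 0

    def test_union_bound_on_flag_fractions(self, rng):
        df = self._table(200, rng)
        out, summary = flag_outliers(df)
        assert summary["stage1_fraction"] <= 0.04 + 1e-9
        assert summary["stage2_fraction"] <= 0.02 + 1e-9

    def test_spiked_subjects_flagged_in_right_stage(self, rng):
        df = self._table(100, rng, image_fusion_cost=[7], smoothness_cost=[42])
        out, _ = flag_outliers(df)
        assert out.loc[7, "stage1_flag"]
        assert out.loc[42, "stage2_flag"] and not out.loc[42, "stage1_flag"]
        assert out.loc[[7, 42], "excluded"].all()

    def test_stage2_quantiles_over_survivors_only(self, rng):
        # a stage-1 outlier with a huge smoothness cost must not eat the
        # stage-2 budget of the survivors
        df = self._table(100, rng, image_fusion_cost=[3], smoothness_cost=[3, 55])
        out, _ = flag_outliers(df)
        assert out.loc[3, "stage1_flag"]
        assert out.loc[55, "stage2_flag"]

    def test_excluded_is_union_of_stages(self, rng):
        df = self._table(60, rng, location_cost=[1], scrap_cost=[2])
        out, summary = flag_outliers(df)
        assert (out["excluded"] == (out["stage1_flag"] | out["stage2_flag"])).all()
        assert summary["retained"] + summary["excluded"] == 60

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(ValueError, match="small"):
            flag_outliers(self._table(5, rng))
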