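"""Algorithmic quality ratings and two-stage percentile outlier flagging.

Five rule-based cost terms are computed per subject (higher = worse):

* **image fusion cost** — mean absolute water-signal difference between the
  two stations over their overlapping slices; motion between breath-holds
  drives this up.
* **segmentation fusion cost** — 1 − Dice between the two stations' labels
  restricted to the overlap (0 when both are empty there).
* **location cost** — longitudinal offset of the segmentation's centre of
  mass from the fused volume's centre line, normalized to half the extent
  (in [0, 1]); kidneys at the top/bottom edge may extend beyond the field of
  view.
* **smoothness cost** — mean absolute slice-to-slice change of the labelled
  in-plane area divided by the mean labelled area over the active range;
  abrupt jumps betray slice-wise 2.5D failures.
* **scrap cost** — share of labelled voxels outside the two largest
  connected components.

Flagging is cohort-wise and two-staged: stage 1 flags the worst tails of the
location / image-fusion / segmentation-fusion costs; stage 2 re-examines the
stage-1 survivors and flags the worst tails of smoothness and scrap cost. A
subject is flagged only when its cost lies strictly above the percentile
threshold, so an all-identical cohort flags nobody.

These cost definitions are the package's normative definitions,
reconstructed from the published prose descriptions of the ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import connected_components
from .image import LabelVolume, VolumeImage

__all__ = [
    "QualityRatings",
    "image_fusion_cost",
    "segmentation_fusion_cost",
    "location_cost",
    "smoothness_cost",
    "scrap_cost",
    "rate_subject",
    "flag_outliers",
    "STAGE1_PERCENTILES",
    "STAGE2_PERCENTILES",
]

#: worst-tail fractions flagged in each stage
STAGE1_PERCENTILES = {"location": 0.01, "image_fusion": 0.01, "segmentation_fusion": 0.02}
STAGE2_PERCENTILES = {"smoothness": 0.01, "scrap": 0.01}


@dataclass
class QualityRatings:
    image_fusion_cost: float
    segmentation_fusion_cost: float
    location_cost: float
    smoothness_cost: float
    scrap_cost: float
    stage1_flag: bool = False
    stage2_flag: bool = False
    reason: str = ""

    @property
    def excluded(self) -> bool:
        return self.stage1_flag or self.stage2_flag

    def to_dict(self) -> dict:
        return {
            "image_fusion_cost": self.image_fusion_cost,
            "segmentation_fusion_cost": self.segmentation_fusion_cost,
            "location_cost": self.location_cost,
            "smoothness_cost": self.smoothness_cost,
            "scrap_cost": self.scrap_cost,
            "stage1_flag": self.stage1_flag,
            "stage2_flag": self.stage2_flag,
            "excluded": self.excluded,
            "reason": self.reason,
        }


def _overlap_slices(a, b) -> tuple[int, int, int]:
    """(#slices, start index in a, start index in b) of the z-overlap."""
    sz = a.spacing_mm[2]
    k = int(round((b.origin_mm[2] - a.origin_mm[2]) / sz))
    if k >= 0:
        n = min(a.data.shape[2] - k, b.data.shape[2])
        return max(n, 0), k, 0
    n = min(a.data.shape[2], b.data.shape[2] + k)
    return max(n, 0), 0, -k


def image_fusion_cost(a: VolumeImage, b: VolumeImage) -> float:
    """Mean absolute intensity difference over the station overlap.

    Stations should be normalized to [0, 1] first so the cost is comparable
    across subjects.
    """
    n, ka, kb = _overlap_slices(a, b)
    if n <= 0:
        raise ValueError("stations have an empty overlap; flag subject for manual review")
    da = np.asarray(a.data[:, :, ka : ka + n], dtype=np.float64)
    db = np.asarray(b.data[:, :, kb : kb + n], dtype=np.float64)
    return float(np.abs(da - db).mean())


def segmentation_fusion_cost(labels_a: LabelVolume, labels_b: LabelVolume) -> float:
    """1 − Dice between the two stations' binary labels on the overlap."""
    n, ka, kb = _overlap_slices(labels_a, labels_b)
    if n <= 0:
        raise ValueError("stations have an empty overlap")
    ma = labels_a.as_bool()[:, :, ka : ka + n]
    mb = labels_b.as_bool()[:, :, kb : kb + n]
    sa, sb = int(ma.sum()), int(mb.sum())
    if sa + sb == 0:
        return 0.0
    inter = int((ma & mb).sum())
    return 1.0 - 2.0 * inter / (sa + sb)


def location_cost(fused_labels: LabelVolume) -> float:
    """Normalized longitudinal offset of the label COM from the centre line.

    0 at the volume midpoint, 1 at either longitudinal edge. An empty mask
    rates worst (1.0).
    """
    mask = fused_labels.as_bool()
    if not mask.any():
        return 1.0
    nz = mask.shape[2]
    z_com = float(np.nonzero(mask)[2].mean())
    z_mid = (nz - 1) / 2.0
    half = nz / 2.0
    return float(min(abs(z_com - z_mid) / half, 1.0))


def smoothness_cost(fused_labels: LabelVolume) -> float:
    """Mean |area(z+1) − area(z)| over the active slice range / mean area."""
    mask = fused_labels.as_bool()
    areas = mask.sum(axis=(0, 1)).astype(np.float64)
    active = np.flatnonzero(areas)
    if active.size == 0:
        return 0.0
    z0, z1 = active[0], active[-1]
    a = areas[z0 : z1 + 1]
    if a.size < 2:
        warnings.warn("single-slice mask: smoothness cost is 0", stacklevel=2)
        return 0.0
    return float(np.abs(np.diff(a)).mean() / a.mean())


def scrap_cost(fused_labels: LabelVolume, connectivity: int = 6) -> float:
    """Share of labelled voxels outside the two largest components."""
    total = int(fused_labels.as_bool().sum())
    if total == 0:
        return 0.0
    comps = connected_components(fused_labels, connectivity)
    if len(comps) <= 2:
        return 0.0
    kept = sum(int(c.sum()) for c in comps[:2])
    return (total - kept) / total


def rate_subject(
    water_a: VolumeImage,
    water_b: VolumeImage,
    labels_a: LabelVolume,
    labels_b: LabelVolume,
    fused_labels: LabelVolume,
) -> QualityRatings:
    """All five cost terms for one subject (stations already normalized)."""
    return QualityRatings(
        image_fusion_cost=image_fusion_cost(water_a, water_b),
        segmentation_fusion_cost=segmentation_fusion_cost(labels_a, labels_b),
        location_cost=location_cost(fused_labels),
        smoothness_cost=smoothness_cost(fused_labels),
        scrap_cost=scrap_cost(fused_labels),
    )


_STAGE1_COLS = {
    "location": "location_cost",
    "image_fusion": "image_fusion_cost",
    "segmentation_fusion": "segmentation_fusion_cost",
}
_STAGE2_COLS = {"smoothness": "smoothness_cost", "scrap": "scrap_cost"}


def _tail_flags(values: pd.Series, fraction: float) -> pd.Series:
    """Flag at most floor(fraction * n) strictly-worst subjects.

    The threshold is the (k+1)-th largest cost; only strictly larger values
    are flagged, so ties at the boundary (and all-identical cohorts) flag
    fewer or none, and the flagged fraction never exceeds ``fraction``.
    """
    n = len(values)
    if n < 2 or fraction <= 0:
        return pd.Series(False, index=values.index)
    # "top f of worst" is at least the single worst subject on small cohorts
    k = max(1, int(np.floor(fraction * n)))
    threshold = values.nlargest(k + 1).iloc[-1]
    return values > threshold


def flag_outliers(
    ratings: pd.DataFrame,
    stage1_percentiles: dict[str, float] | None = None,
    stage2_percentiles: dict[str, float] | None = None,
):
    """Two-stage percentile flagging over a cohort ratings table.

    ``ratings`` needs the five ``*_cost`` columns (and optionally
    ``subject_id``). Returns ``(flagged_table, summary)``: the table gains
    stage1_flag / stage2_flag / excluded columns; the summary reports flagged
    fractions per stage and overall. Stage-2 quantiles are computed over
    stage-1 survivors only.
    """
    if len(ratings) < 10:
        raise ValueError("cohort too small for percentile-based flagging (need >= 10)")
    s1 = stage1_percentiles or STAGE1_PERCENTILES
    s2 = stage2_percentiles or STAGE2_PERCENTILES

    out = ratings.copy()
    stage1 = pd.Series(False, index=out.index)
    for key, frac in s1.items():
        stage1 |= _tail_flags(out[_STAGE1_COLS[key]], frac)
    out["stage1_flag"] = stage1

    survivors = out.index[~stage1]
    stage2 = pd.Series(False, index=out.index)
    for key, frac in s2.items():
        stage2.loc[survivors] |= _tail_flags(out.loc[survivors, _STAGE2_COLS[key]], frac)
    out["stage2_flag"] = stage2
    out["excluded"] = stage1 | stage2
    # manual override hook: flagged-but-small subjects can be re-included by hand
    if "manual_reinclude" not in out.columns:
        out["manual_reinclude"] = False

    n = len(out)
    summary = {
        "n": n,
        "stage1_flagged": int(stage1.sum()),
        "stage1_fraction": float(stage1.mean()),
        "stage2_flagged": int(stage2.sum()),
        "stage2_fraction": float(stage2.mean()),
        "excluded": int(out["excluded"].sum()),
        "excluded_fraction": float(out["excluded"].mean()),
        "retained": int(n - out["excluded"].sum()),
    }
    return out, summary
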