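"""Validation metrics against reference masks and cross-validation designs.

Overlap quality is scored with the Sørensen–Dice coefficient and Jaccard
index; volume agreement with the mean absolute error (MAE), a symmetric mean
absolute percentage error (SMAPE — the absolute difference divided by the
mean of prediction and reference, robust to which of the two is treated as
truth), the coefficient of determination R², and Bland–Altman 95% limits of
agreement on differences d = reference − predicted (so systematic
oversegmentation shifts the interval negative). All metrics are computed on
fused subject volumes, never per station.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import fuse_stations, measure
from .image import LabelVolume

__all__ = [
    "dice",
    "jaccard",
    "smape",
    "aggregate",
    "AggregateMetrics",
    "ValidationReport",
    "CrossValPlan",
    "cross_validate",
]


def _masks(pred, ref):
    a = pred.as_bool() if isinstance(pred, LabelVolume) else np.asarray(pred).astype(bool)
    b = ref.as_bool() if isinstance(ref, LabelVolume) else np.asarray(ref).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(pred, ref, empty_value: float = 1.0) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|).

    Two empty masks score ``empty_value`` (default 1.0: perfect agreement;
    set 0.0 for the strict convention).
    """
    a, b = _masks(pred, ref)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return empty_value
    return 2.0 * int((a & b).sum()) / (sa + sb)


def jaccard(pred, ref, empty_value: float = 1.0) -> float:
    """Jaccard index |A∩B| / |A∪B| (equals D / (2 − D))."""
    a, b = _masks(pred, ref)
    union = int((a | b).sum())
    if union == 0:
        return empty_value
    return int((a & b).sum()) / union


def smape(pred_vol: float, ref_vol: float) -> float:
    """Symmetric percentage error: |pred − ref| / mean(pred, ref) × 100.

    E.g. a 25 cm³ absolute difference on a pair with mean 250 cm³ is 10%.
    Both zero returns 0 by convention (with a warning).
    """
    if pred_vol + ref_vol == 0:
        warnings.warn("SMAPE of a (0, 0) pair is defined as 0", stacklevel=2)
        return 0.0
    if pred_vol < 0 or ref_vol < 0:
        raise ValueError("volumes must be non-negative")
    return abs(pred_vol - ref_vol) / ((pred_vol + ref_vol) / 2.0) * 100.0


@dataclass
class AggregateMetrics:
    mae_cm3: float
    smape_pct: float
    r2: float | None
    loa_low_cm3: float
    loa_high_cm3: float
    bias_cm3: float
    n: int


def aggregate(pairs) -> AggregateMetrics:
    """Cohort-level volume agreement from (predicted, reference) cm³ pairs.

    LoA = mean(d) ± 1.96·SD(d) with d = reference − predicted and the sample
    (ddof=1) standard deviation; R² = 1 − Σd² / Σ(ref − mean ref)², reported
    as absent when the references are constant.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (pred, ref) pairs")
    pred, ref = arr[:, 0], arr[:, 1]
    d = ref - pred
    mae = float(np.abs(d).mean())
    smape_mean = float(np.mean([smape(p, r) for p, r in arr]))
    ss_tot = float(((ref - ref.mean()) ** 2).sum())
    r2 = None if ss_tot == 0 else float(1.0 - (d**2).sum() / ss_tot)
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    bias = float(d.mean())
    return AggregateMetrics(
        mae_cm3=mae,
        smape_pct=smape_mean,
        r2=r2,
        loa_low_cm3=bias - 1.96 * sd,
        loa_high_cm3=bias + 1.96 * sd,
        bias_cm3=bias,
        n=len(d),
    )


@dataclass
class ValidationReport:
    """Per-subject rows plus the aggregate volume-agreement metrics."""

    per_subject: pd.DataFrame
    metrics: AggregateMetrics

    def bland_altman_table(self) -> pd.DataFrame:
        t = self.per_subject
        return pd.DataFrame(
            {
                "subject_id": t["subject_id"],
                "mean_cm3": (t["pred_combined_cm3"] + t["ref_combined_cm3"]) / 2.0,
                "difference_cm3": t["ref_combined_cm3"] - t["pred_combined_cm3"],
            }
        )


def score_subject(pred_fused: LabelVolume, ref_fused: LabelVolume, subject_id="") -> dict:
    """Dice/Jaccard and combined predicted vs reference volume for one subject."""
    return {
        "subject_id": subject_id,
        "dice": dice(pred_fused, ref_fused),
        "jaccard": jaccard(pred_fused, ref_fused),
        "pred_combined_cm3": pred_fused.volume_cm3(),
        "ref_combined_cm3": ref_fused.volume_cm3(),
    }


def build_report(rows) -> ValidationReport:
    table = pd.DataFrame(list(rows))
    metrics = aggregate(zip(table["pred_combined_cm3"], table["ref_combined_cm3"]))
    return ValidationReport(table, metrics)


@dataclass
class CrossValPlan:
    """Subject-level k-fold split with an optional training-only extra pool.

    The extra pool mimics a second, harder reference set that is added to
    every fold's training data but never validated on.
    """

    k: int = 8
    seed: int = 0
    extra_pool: list | None = None

    def folds(self, subject_ids) -> list[list]:
        ids = list(subject_ids)
        if self.extra_pool:
            overlap = set(ids) & set(self.extra_pool)
            if overlap:
                raise ValueError(f"extra pool overlaps the primary set: {sorted(overlap)}")
        if len(ids) < self.k:
            raise ValueError(f"{len(ids)} subjects cannot form {self.k} folds")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(ids))
        folds: list[list] = [[] for _ in range(self.k)]
        for pos, idx in enumerate(order):
            folds[pos % self.k].append(ids[idx])
        return folds


def _training_samples(subjects, drop_ends: int, pad_multiple: int):
    from .preprocess import build_stack, normalize_station, select_training_slices

    samples = []
    for subj in subjects:
        for si, (station, truth) in enumerate(
            ((subj.station_a["water"], subj.truth_a), (subj.station_b["water"], subj.truth_b))
        ):
            norm = normalize_station(station)
            for i in select_training_slices(norm, drop_ends):
                stack = build_stack(norm, int(i), pad_multiple, station_index=si)
                label = np.pad(truth.as_bool()[:, :, int(i)].astype(np.uint8),
                               stack.pad_spec)
                samples.append((stack, label))
    return samples


def predict_subject(model, subject):
    """Full inference path for one phantom: predict both stations, fuse."""
    from .model import predict_station

    _, prob_a = predict_station(model, subject.station_a["water"])
    _, prob_b = predict_station(model, subject.station_b["water"])
    return fuse_stations(
        subject.station_a["water"], subject.station_b["water"], prob_a, prob_b
    )


def cross_validate(subjects, plan: CrossValPlan, net_spec, train_cfg,
                   extra_subjects=()) -> tuple[list[ValidationReport], ValidationReport]:
    """k-fold cross-validation through the full train → fuse → score path.

    For each fold a fresh network instance is trained on the slices of all
    other folds (plus any training-only extra subjects), the held-out
    subjects are segmented station-wise, fused, and scored against their
    fused ground truth. Returns (per-fold reports, pooled report).
    """
    from .model import build_network, train as train_model

    by_id = {s.metadata.get("subject_id", f"S{i:04d}"): s for i, s in enumerate(subjects)}
    plan = CrossValPlan(plan.k, plan.seed, [s.metadata.get("subject_id") for s in extra_subjects] or None)
    folds = plan.folds(list(by_id))
    fold_reports, pooled_rows = [], []
    for f, held_out in enumerate(folds):
        if not held_out:
            raise ValueError(f"fold {f} has no subjects")
        train_ids = [sid for fold in folds for sid in fold if fold is not folds[f]]
        train_subjects = [by_id[sid] for sid in train_ids] + list(extra_subjects)
        spec = type(net_spec)(**{**net_spec.__dict__, "seed": net_spec.seed + f})
        model = build_network(spec)
        samples = _training_samples(train_subjects, train_cfg.drop_ends, spec.downsampling_factor)
        model, _ = train_model(model, samples, train_cfg)
        rows = []
        for sid in held_out:
            subj = by_id[sid]
            fused = predict_subject(model, subj)
            rows.append(score_subject(fused.fused_labels, subj.truth_fused, sid))
        fold_reports.append(build_report(rows))
        pooled_rows.extend(rows)
    return fold_reports, build_report(pooled_rows)
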