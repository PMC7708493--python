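"""Seeded synthetic dual-station abdominal MRI phantoms with voxel ground truth.

Each phantom emulates the acquisition geometry of dual-echo neck-to-knee body
MRI around the kidneys: two overlapping axial imaging stations (each acquired
in its own breath-hold), a water channel in which parenchymal kidney tissue is
bright, a fat channel in which it is dark, dark internal structures
(pelvis/calyces rendered as an excluded medial concavity), additive noise, and
an optional rigid breath-hold misalignment applied to the second station's
content. Anomalies (missing kidney, cysts, renal fusion, truncation at the
station border) can be injected to exercise quality control.

Kidneys are modelled as superellipsoids (exponent ~2.5, boxier than an
ellipsoid) minus an interior ellipsoidal hilum, so that bright parenchyma
surrounds a dark pelvis — matching a parenchyma-only segmentation protocol in
which cysts, calyces, ureters and major vessels are excluded.

The scene is generated analytically on a whole-trunk grid and then split into
two stations, so station content, per-station truth and whole-volume truth are
mutually consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image import LabelVolume, VolumeImage

__all__ = [
    "IntensityParams",
    "PhantomConfig",
    "SubjectPhantom",
    "generate_subject",
    "generate_cohort",
    "true_volume",
    "write_cohort",
]

ANOMALIES = ("none", "missing_left", "missing_right", "cysts", "fused", "border_truncation")

#: Rigid offset (AP, LR, SI) in mm used for the "large_motion" cohort tag —
#: large enough to visibly break station agreement in the overlap.
LARGE_MOTION_MM = (6.0, 0.0, 9.0)


@dataclass
class IntensityParams:
    """Mean signal levels (arbitrary units) for the phantom tissue classes."""

    air: float = 0.05
    tissue: float = 0.35          # generic background trunk tissue, water channel
    parenchyma: float = 0.85      # bright kidney cortex+medulla, water channel
    dark_structure: float = 0.12  # pelvis / calyces / cysts, water channel
    fat_tissue: float = 0.75      # trunk in the fat channel
    fat_kidney: float = 0.10      # kidneys are dark in fat


@dataclass
class PhantomConfig:
    """Geometry, intensity and anomaly settings for one synthetic subject.

    The default grid mirrors a typical abdominal station layout: stations of
    224 x 174 x 44 voxels at (2.232, 2.232, 4.5) mm, two stations overlapping
    by 24 slices on a 64-slice whole-trunk grid (2*44 - 24 = 64).
    """

    grid_shape: tuple[int, int, int] = (224, 174, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.232, 2.232, 4.5)
    station_slices: int = 44
    overlap_slices: int = 24
    #: semi-axis sampling ranges in mm per axis (AP, LR, SI)
    kidney_size_range: tuple[tuple[float, float], ...] = ((17.0, 23.0), (26.0, 33.0), (46.0, 58.0))
    hilum_fraction: float = 0.5
    superellipsoid_exponent: float = 2.5
    intensity_params: IntensityParams = field(default_factory=IntensityParams)
    noise_sd: float = 0.03
    motion_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    anomaly: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anomaly not in ANOMALIES:
            raise ValueError(f"unknown anomaly {self.anomaly!r}; choose from {ANOMALIES}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        nz = self.grid_shape[2]
        if self.station_slices > nz:
            raise ValueError("station_slices exceeds grid z-extent")
        if not (0 < self.overlap_slices < self.station_slices):
            raise ValueError("need 0 < overlap_slices < station_slices")
        if 2 * self.station_slices - self.overlap_slices != nz:
            raise ValueError(
                "inconsistent station geometry: 2*station_slices - overlap_slices "
                f"= {2 * self.station_slices - self.overlap_slices} != grid z-extent {nz}"
            )

    @classmethod
    def desk_scale(cls, **overrides) -> "PhantomConfig":
        """A coarse-voxel configuration small enough for CPU-only runs.

        Anatomical sizes stay in mm; only the voxel grid is coarser:
        64 x 54 x 24 voxels at (4.5, 4.5, 6.0) mm, stations of 16 slices
        overlapping by 8.
        """
        base = dict(
            grid_shape=(64, 54, 24),
            voxel_spacing_mm=(4.5, 4.5, 6.0),
            station_slices=16,
            overlap_slices=8,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SubjectPhantom:
    """One generated subject: two stations, per-station and fused truth."""

    station_a: dict[str, VolumeImage]  # keys: water, fat
    station_b: dict[str, VolumeImage]
    truth_a: LabelVolume
    truth_b: LabelVolume
    truth_fused: LabelVolume  # on the whole-trunk (union) grid, motion-free
    true_left_volume_cm3: float
    true_right_volume_cm3: float
    metadata: dict

    @property
    def true_combined_volume_cm3(self) -> float:
        return self.true_left_volume_cm3 + self.true_right_volume_cm3


def true_volume(truth: LabelVolume, spacing_mm: tuple[float, float, float]) -> float:
    """Voxel-count volume of a binary mask in cm^3 (empty mask -> 0)."""
    count = int(np.asarray(truth.data if isinstance(truth, LabelVolume) else truth).astype(bool).sum())
    sx, sy, sz = spacing_mm
    return count * sx * sy * sz / 1000.0


def _superellipsoid(coords, center, semi, exponent):
    """Inside-mask of |dx/a|^e + |dy/b|^e + |dz/c|^e <= 1."""
    terms = [
        np.abs((coords[ax] - center[ax]) / semi[ax]) ** exponent for ax in range(3)
    ]
    return (terms[0] + terms[1] + terms[2]) <= 1.0


def _ellipsoid(coords, center, semi):
    return _superellipsoid(coords, center, semi, 2.0)


class _SubjectGeometry:
    """All randomly sampled anatomy for one subject, in physical mm."""

    def __init__(self, cfg: PhantomConfig, rng: np.random.Generator):
        nx, ny, nz = cfg.grid_shape
        sx, sy, sz = cfg.voxel_spacing_mm
        ext = (nx * sx, ny * sy, nz * sz)
        self.extent = ext
        self.trunk_center = (ext[0] / 2, ext[1] / 2, ext[2] / 2)
        self.trunk_semi = (0.44 * ext[0], 0.46 * ext[1])

        lo = [r[0] for r in cfg.kidney_size_range]
        hi = [r[1] for r in cfg.kidney_size_range]
        # right kidney = low column index, left = high column index
        self.semi = {}
        self.center = {}
        lr_off = 0.19 * ext[1] + rng.uniform(-4.0, 4.0)
        for side, sign in (("right", -1.0), ("left", +1.0)):
            semi = tuple(rng.uniform(l, h) for l, h in zip(lo, hi))
            cz = ext[2] / 2 + rng.uniform(-0.05, 0.05) * ext[2]
            cx = ext[0] / 2 + 0.06 * ext[0] + rng.uniform(-3.0, 3.0)
            cy = ext[1] / 2 + sign * lr_off + rng.uniform(-3.0, 3.0)
            if cfg.anomaly == "border_truncation":
                # push the kidney onto the outer edge of station A
                cz = 0.55 * semi[2]
            self.center[side] = (cx, cy, cz)
            self.semi[side] = semi

        self.cysts = []
        if cfg.anomaly == "cysts":
            side = "left" if rng.random() < 0.5 else "right"
            n_cysts = int(rng.integers(2, 5))
            for _ in range(n_cysts):
                c = self.center[side]
                s = self.semi[side]
                pos = tuple(
                    c[ax] + rng.uniform(-0.6, 0.6) * s[ax] for ax in range(3)
                )
                self.cysts.append((pos, rng.uniform(6.0, 12.0)))


def _render_scene(cfg: PhantomConfig, geom: _SubjectGeometry, shift_mm=(0.0, 0.0, 0.0)):
    """Noiseless water/fat scene and truth mask, content shifted rigidly by shift_mm.

    The shift moves the *content* (trunk and kidneys) relative to the grid —
    the analytic analogue of the subject moving between breath-holds.
    """
    nx, ny, nz = cfg.grid_shape
    sx, sy, sz = cfg.voxel_spacing_mm
    ip = cfg.intensity_params
    axes = [
        (np.arange(nx) + 0.5) * sx - shift_mm[0],
        (np.arange(ny) + 0.5) * sy - shift_mm[1],
        (np.arange(nz) + 0.5) * sz - shift_mm[2],
    ]
    coords = np.meshgrid(*axes, indexing="ij", sparse=True)

    # trunk: elliptic cylinder along z
    trunk = (
        ((coords[0] - geom.trunk_center[0]) / geom.trunk_semi[0]) ** 2
        + ((coords[1] - geom.trunk_center[1]) / geom.trunk_semi[1]) ** 2
    ) <= 1.0
    trunk = np.broadcast_to(trunk, (nx, ny, nz)).copy()

    water = np.full((nx, ny, nz), ip.air, dtype=np.float32)
    fat = np.full((nx, ny, nz), ip.air, dtype=np.float32)
    water[trunk] = ip.tissue
    fat[trunk] = ip.fat_tissue

    truth = np.zeros((nx, ny, nz), dtype=bool)
    sides = ["right", "left"]
    if cfg.anomaly == "missing_left":
        sides.remove("left")
    elif cfg.anomaly == "missing_right":
        sides.remove("right")

    dark = np.zeros_like(truth)
    for side in sides:
        body = _superellipsoid(coords, geom.center[side], geom.semi[side], cfg.superellipsoid_exponent)
        # hilum: medial ellipsoidal concavity, rendered dark and excluded
        c = geom.center[side]
        s = geom.semi[side]
        medial_sign = +1.0 if side == "right" else -1.0  # toward the midline
        hilum_center = (c[0], c[1] + medial_sign * 0.75 * s[1], c[2])
        hilum_semi = tuple(cfg.hilum_fraction * v for v in s)
        hilum = _ellipsoid(coords, hilum_center, hilum_semi)
        parenchyma = body & ~hilum
        # the hilum is a concavity, not an amputation: slivers it would cut
        # off the medial pole are rendered dark, keeping one solid body
        from scipy import ndimage

        labelled, ncomp = ndimage.label(parenchyma, structure=ndimage.generate_binary_structure(3, 1))
        if ncomp > 1:
            largest = 1 + np.argmax(np.bincount(labelled.ravel())[1:])
            parenchyma = labelled == largest
        dark |= body & ~parenchyma
        truth |= parenchyma

    for pos, radius in geom.cysts:
        cyst = _ellipsoid(coords, pos, (radius,) * 3)
        dark |= cyst & truth
        truth &= ~cyst

    if cfg.anomaly == "fused" and len(sides) == 2:
        # bright isthmus joining the medial poles -> one connected component
        c_r = np.asarray(geom.center["right"])
        c_l = np.asarray(geom.center["left"])
        p = np.stack(np.broadcast_arrays(*coords), axis=-1).reshape(-1, 3)
        d = c_l - c_r
        t = np.clip((p - c_r) @ d / (d @ d), 0.0, 1.0)
        dist = np.linalg.norm(p - (c_r + t[:, None] * d), axis=1)
        bridge = (dist <= 9.0).reshape(nx, ny, nz)
        truth |= bridge
        dark &= ~bridge

    water[dark] = ip.dark_structure
    water[truth] = ip.parenchyma
    fat[truth | dark] = ip.fat_kidney
    return water, fat, truth


def _side_volumes(truth: np.ndarray, spacing_mm) -> tuple[float, float]:
    """True left/right volumes from the motion-free whole-grid mask.

    Components split by their column-axis centre of mass (left = larger LR
    index). A fused mask counts once, assigned to the side of its COM.
    """
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    labelled, n = ndimage.label(truth, structure=struct)
    vox = float(np.prod(spacing_mm)) / 1000.0
    mid = truth.shape[1] / 2.0
    left = right = 0.0
    for lab in range(1, n + 1):
        comp = labelled == lab
        com_col = ndimage.center_of_mass(comp)[1]
        vol = comp.sum() * vox
        if com_col >= mid:
            left += vol
        else:
            right += vol
    return left, right


def generate_subject(config: PhantomConfig) -> SubjectPhantom:
    """Generate one seeded dual-station phantom with ground truth.

    Deterministic for a fixed config (seed included); station B content is
    rigidly shifted by ``motion_offset_mm`` before extraction, emulating
    breath-hold misalignment between stations.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    geom = _SubjectGeometry(cfg, rng)

    water0, fat0, truth0 = _render_scene(cfg, geom)
    if any(abs(m) > 0 for m in cfg.motion_offset_mm):
        water_m, fat_m, truth_m = _render_scene(cfg, geom, shift_mm=cfg.motion_offset_mm)
    else:
        water_m, fat_m, truth_m = water0, fat0, truth0

    S = cfg.station_slices
    nz = cfg.grid_shape[2]
    z0_b = nz - S
    sx, sy, sz = cfg.voxel_spacing_mm

    noise = np.random.default_rng(rng.integers(2**31))

    def station(src_water, src_fat, zslice, z_origin):
        out = {}
        for channel, src in (("water", src_water), ("fat", src_fat)):
            data = src[:, :, zslice].copy()
            if cfg.noise_sd > 0:
                data = data + noise.normal(0.0, cfg.noise_sd, data.shape).astype(np.float32)
                np.clip(data, 0.0, None, out=data)
            out[channel] = VolumeImage(
                data, cfg.voxel_spacing_mm, origin_mm=(0.0, 0.0, z_origin), channel=channel
            )
        return out

    sl_a = np.s_[0:S]
    sl_b = np.s_[z0_b : z0_b + S]
    station_a = station(water0, fat0, sl_a, 0.0)
    station_b = station(water_m, fat_m, sl_b, z0_b * sz)

    truth_a = LabelVolume(truth0[:, :, sl_a].copy(), cfg.voxel_spacing_mm, (0, 0, 0.0))
    truth_b = LabelVolume(truth_m[:, :, sl_b].copy(), cfg.voxel_spacing_mm, (0, 0, z0_b * sz))
    truth_fused = LabelVolume(truth0, cfg.voxel_spacing_mm, (0, 0, 0.0))

    left, right = _side_volumes(truth0, cfg.voxel_spacing_mm)
    return SubjectPhantom(
        station_a=station_a,
        station_b=station_b,
        truth_a=truth_a,
        truth_b=truth_b,
        truth_fused=truth_fused,
        true_left_volume_cm3=left,
        true_right_volume_cm3=right,
        metadata={
            "anomaly": cfg.anomaly,
            "motion_offset_mm": tuple(cfg.motion_offset_mm),
            "seed": cfg.seed,
        },
    )


#: per-subject baseline breath-hold misalignment (AP, LR, SI) standard
#: deviations in mm used by :func:`generate_cohort`. Sub-voxel by design:
#: compliant repeat breath-holds align well, and larger misalignment is
#: exactly the failure mode injected separately via the "large_motion" tag.
BASELINE_MOTION_SD_MM = (0.25, 0.0, 0.4)


def generate_cohort(
    n: int,
    config: PhantomConfig | None = None,
    anomaly_rates: dict[str, float] | None = None,
    seed: int = 0,
    baseline_motion_sd_mm: tuple[float, float, float] = BASELINE_MOTION_SD_MM,
):
    """Generate ``n`` phantom subjects plus a manifest DataFrame.

    ``anomaly_rates`` maps anomaly names (the :data:`ANOMALIES` entries plus
    the pseudo-anomaly ``"large_motion"``) to fractions of the cohort; counts
    are ``round(rate * n)`` and assignment to subjects is a deterministic
    seeded shuffle, so the same (n, seed) always yields the same manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or PhantomConfig()
    anomaly_rates = dict(anomaly_rates or {})
    if sum(anomaly_rates.values()) > 1.0 + 1e-9:
        raise ValueError("anomaly rates sum to more than 1")
    for key in anomaly_rates:
        if key != "large_motion" and key not in ANOMALIES:
            raise ValueError(f"unknown anomaly {key!r}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = ["none"] * n
    pos = 0
    for name, rate in anomaly_rates.items():
        count = int(round(rate * n))
        for idx in order[pos : pos + count]:
            assignment[idx] = name
        pos += count

    subjects, rows = [], []
    for i in range(n):
        sub_seed = int(rng.integers(2**31))
        motion = tuple(
            float(rng.normal(0.0, sd)) if sd > 0 else 0.0 for sd in baseline_motion_sd_mm
        )
        anomaly = assignment[i]
        if anomaly == "large_motion":
            motion = LARGE_MOTION_MM
            cfg_anom = "none"
        else:
            cfg_anom = anomaly
        cfg = replace(config, seed=sub_seed, anomaly=cfg_anom, motion_offset_mm=motion)
        subj = generate_subject(cfg)
        subj.metadata["anomaly"] = anomaly  # keep the cohort-level tag
        subj.metadata["subject_id"] = f"S{i:04d}"
        subjects.append(subj)
        rows.append(
            {
                "subject_id": f"S{i:04d}",
                "anomaly": anomaly,
                "seed": sub_seed,
                "motion_ap_mm": motion[0],
                "motion_lr_mm": motion[1],
                "motion_si_mm": motion[2],
                "true_left_cm3": subj.true_left_volume_cm3,
                "true_right_cm3": subj.true_right_volume_cm3,
            }
        )
    manifest = pd.DataFrame(rows)
    return subjects, manifest


def write_cohort(subjects, manifest: pd.DataFrame, out_dir: str | Path) -> pd.DataFrame:
    """Write stations, truth masks and the manifest CSV to ``out_dir``.

    Returns the manifest augmented with file-path columns, as written to
    ``out_dir/manifest.csv``.
    """
    from . import io as kio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths: dict[str, list[str]] = {
        k: [] for k in ("station_a", "station_b", "fat_a", "fat_b", "truth_a", "truth_b", "truth_fused")
    }
    for subj in subjects:
        sid = subj.metadata["subject_id"]
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        entries = {
            "station_a": (subj.station_a["water"], "water_a.nii.gz"),
            "station_b": (subj.station_b["water"], "water_b.nii.gz"),
            "fat_a": (subj.station_a["fat"], "fat_a.nii.gz"),
            "fat_b": (subj.station_b["fat"], "fat_b.nii.gz"),
        }
        for key, (vol, name) in entries.items():
            kio.write_volume(vol, sdir / name)
            paths[key].append(str(sdir / name))
        for key, lab, name in (
            ("truth_a", subj.truth_a, "truth_a.nii.gz"),
            ("truth_b", subj.truth_b, "truth_b.nii.gz"),
            ("truth_fused", subj.truth_fused, "truth_fused.nii.gz"),
        ):
            kio.write_label(lab, sdir / name)
            paths[key].append(str(sdir / name))
    for key, col in paths.items():
        manifest[key] = col
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
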