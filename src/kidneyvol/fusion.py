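"""Station fusion onto a common grid, connected components, and volumetry.

The two stations of a subject share the in-plane grid and spacing and
overlap along the longitudinal axis; their origins place them on a common
voxel grid (the union of both extents). Outside the overlap each station is
copied verbatim; inside it, intensities and label probabilities are blended
with a linear ramp weight running 0 -> 1 across the overlap toward the
nearer station interior, and blended label probabilities are thresholded at
0.5 (>= is kidney).

Measurement then extracts the two largest face-connected (6-neighbour)
components — assumed to be the kidneys — identifies left vs right by the
column-axis centre of mass (the subject's left lies at increasing column
index), and reports voxel-count volumes, centres of mass in mm, the
inter-kidney Euclidean distance, and the scrap fraction (labelled voxels
outside the two largest components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import LabelVolume, VolumeImage

__all__ = ["FusedSubject", "KidneyMeasurement", "fuse_stations", "connected_components", "measure"]


@dataclass
class FusedSubject:
    fused_water: VolumeImage
    fused_labels: LabelVolume        # binary, after thresholding
    fused_probabilities: LabelVolume
    overlap_range: tuple[int, int]   # [start, stop) slices on the union grid


@dataclass
class KidneyMeasurement:
    left_volume_cm3: float
    right_volume_cm3: float
    combined_volume_cm3: float
    left_com_mm: tuple[float, float, float] | None
    right_com_mm: tuple[float, float, float] | None
    distance_mm: float | None
    relative_offset_mm: tuple[float, float, float] | None
    scrap_fraction: float
    n_components: int

    def to_dict(self) -> dict:
        d = {
            "left_cm3": self.left_volume_cm3,
            "right_cm3": self.right_volume_cm3,
            "combined_cm3": self.combined_volume_cm3,
            "distance_mm": self.distance_mm,
            "scrap_fraction": self.scrap_fraction,
            "n_components": self.n_components,
        }
        off = self.relative_offset_mm or (None, None, None)
        d.update({"offset_ap_mm": off[0], "offset_lr_mm": off[1], "offset_si_mm": off[2]})
        return d


def _z_index_offset(a: VolumeImage, b) -> int:
    sz = a.spacing_mm[2]
    shift = (b.origin_mm[2] - a.origin_mm[2]) / sz
    k = int(round(shift))
    if abs(shift - k) > 1e-3:
        raise ValueError("station origins are not aligned to the common voxel grid")
    return k


def fuse_stations(
    a: VolumeImage,
    b: VolumeImage,
    labels_a: LabelVolume,
    labels_b: LabelVolume,
) -> FusedSubject:
    """Fuse two overlapping stations (and their label probabilities).

    ``labels_*`` may be binary or probabilistic; they are blended as
    probabilities with the same ramp weights as the intensities and
    thresholded at 0.5. Zero overlap degrades to plain concatenation with a
    warning.
    """
    if a.data.shape[:2] != b.data.shape[:2]:
        raise ValueError(f"in-plane dims differ: {a.data.shape[:2]} vs {b.data.shape[:2]}")
    if not np.allclose(a.spacing_mm, b.spacing_mm):
        raise ValueError(f"spacing differs: {a.spacing_mm} vs {b.spacing_mm}")
    if a.origin_mm[2] > b.origin_mm[2]:  # keep a as the superior station
        return fuse_stations(b, a, labels_b, labels_a)

    k0 = _z_index_offset(a, b)
    Sa, Sb = a.data.shape[2], b.data.shape[2]
    nz = max(Sa, k0 + Sb)
    ov_start, ov_stop = k0, min(Sa, k0 + Sb)
    L = ov_stop - ov_start
    if L <= 0:
        warnings.warn("stations do not overlap; concatenating without blending", stacklevel=2)
        ov_start = ov_stop = min(Sa, k0)

    shape = (*a.data.shape[:2], nz)
    water = np.zeros(shape, dtype=np.float32)
    prob = np.zeros(shape, dtype=np.float32)
    pa = np.asarray(labels_a.data, dtype=np.float32)
    pb = np.asarray(labels_b.data, dtype=np.float32)

    water[:, :, :Sa] = a.data
    prob[:, :, :Sa] = pa
    water[:, :, k0 : k0 + Sb] = b.data
    prob[:, :, k0 : k0 + Sb] = pb
    for t in range(L):
        z = ov_start + t
        wb = (t + 1.0) / (L + 1.0)  # ramp 0 -> 1 toward station b's interior
        wa = 1.0 - wb
        water[:, :, z] = wa * a.data[:, :, z] + wb * b.data[:, :, z - k0]
        prob[:, :, z] = wa * pa[:, :, z] + wb * pb[:, :, z - k0]

    spacing = a.spacing_mm
    origin = a.origin_mm
    return FusedSubject(
        fused_water=VolumeImage(water, spacing, origin, channel=a.channel),
        fused_labels=LabelVolume((prob >= 0.5).astype(np.uint8), spacing, origin),
        fused_probabilities=LabelVolume(prob, spacing, origin),
        overlap_range=(ov_start, ov_stop),
    )


_STRUCTS = {6: ndimage.generate_binary_structure(3, 1),
            18: ndimage.generate_binary_structure(3, 2),
            26: ndimage.generate_binary_structure(3, 3)}


def connected_components(labels: LabelVolume | np.ndarray, connectivity: int = 6):
    """Connected components of a binary mask, largest first.

    Face connectivity (6 neighbours) by default, so diagonal-only touching
    voxels belong to separate components. Ties in size are broken by the
    smallest minimum linear voxel index, making the ordering deterministic.
    Returns a list of boolean masks.
    """
    mask = labels.as_bool() if isinstance(labels, LabelVolume) else np.asarray(labels).astype(bool)
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
    labelled, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if n == 0:
        return []
    flat = labelled.ravel()
    sizes = np.bincount(flat)[1:]
    nz = np.flatnonzero(flat)
    labs, first = np.unique(flat[nz], return_index=True)
    first_index = np.empty(n, dtype=np.int64)
    first_index[labs - 1] = nz[first]  # first linear index per label
    rank = sorted(range(n), key=lambda i: (-sizes[i], first_index[i]))
    return [labelled == (i + 1) for i in rank]


def _com_mm(mask: np.ndarray, spacing, origin) -> tuple[float, float, float]:
    com = ndimage.center_of_mass(mask)
    return tuple(float(c * s + o) for c, s, o in zip(com, spacing, origin))


def measure(fused: FusedSubject, connectivity: int = 6) -> KidneyMeasurement:
    """Volumes, centres of mass and inter-kidney geometry from fused labels.

    With a single component (missing kidney) the side is assigned by the
    component's position relative to the volume's column midline and the
    other side reports volume 0 with absent COM/distance.
    """
    labels = fused.fused_labels
    spacing, origin = labels.spacing_mm, labels.origin_mm
    comps = connected_components(labels, connectivity)
    vox_cm3 = labels.voxel_volume_mm3 / 1000.0
    total = int(labels.as_bool().sum())

    if not comps:
        return KidneyMeasurement(0.0, 0.0, 0.0, None, None, None, None, 0.0, 0)

    main = comps[:2]
    scrap = total - sum(int(c.sum()) for c in main)
    scrap_fraction = scrap / total if total else 0.0

    if len(main) == 1:
        mask = main[0]
        com = _com_mm(mask, spacing, origin)
        vol = float(mask.sum()) * vox_cm3
        mid_mm = origin[1] + spacing[1] * labels.shape[1] / 2.0
        if com[1] >= mid_mm:
            left, right = (vol, com), (0.0, None)
        else:
            left, right = (0.0, None), (vol, com)
        return KidneyMeasurement(
            left[0], right[0], vol, left[1], right[1], None, None,
            scrap_fraction, len(comps),
        )

    coms = [_com_mm(m, spacing, origin) for m in main]
    vols = [float(m.sum()) * vox_cm3 for m in main]
    # subject's left kidney = larger column-axis (LR) centre of mass
    li = 0 if coms[0][1] >= coms[1][1] else 1
    ri = 1 - li
    offset = tuple(l - r for l, r in zip(coms[li], coms[ri]))
    distance = float(np.linalg.norm(offset))
    return KidneyMeasurement(
        left_volume_cm3=vols[li],
        right_volume_cm3=vols[ri],
        combined_volume_cm3=vols[li] + vols[ri],
        left_com_mm=coms[li],
        right_com_mm=coms[ri],
        distance_mm=distance,
        relative_offset_mm=offset,
        scrap_fraction=scrap_fraction,
        n_components=len(comps),
    )
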