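"""Reading and writing station volumes, label masks and cohort manifests.

NIfTI (.nii / .nii.gz) is the canonical on-disk format; a directory of
per-slice DICOM files can be read as a convenience importer. Manifests are
plain CSV files enumerating the subjects of a cohort and the station file
paths belonging to each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import LabelVolume, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_label",
    "write_label",
    "CohortManifest",
    "load_manifest",
]

log = logging.getLogger(__name__)

_REQUIRED_MANIFEST_COLUMNS = ("subject_id", "station_a", "station_b")


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI header of {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for f in files:
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise IOError(f"no readable DICOM slices found in {path}")
    # Sort slices along the patient z axis; fall back to InstanceNumber.
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    except Exception:
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    data = np.stack([d.pixel_array.astype(np.float32) for d in datasets], axis=-1)
    first = datasets[0]
    row_mm, col_mm = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        try:
            dz = abs(
                float(datasets[1].ImagePositionPatient[2])
                - float(first.ImagePositionPatient[2])
            )
        except Exception:
            dz = float(getattr(first, "SliceThickness", 1.0))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    try:
        ox, oy, oz = (float(v) for v in first.ImagePositionPatient)
    except Exception:
        ox = oy = oz = 0.0
    return data, (row_mm, col_mm, dz), (ox, oy, oz)


def read_volume(path: str | Path, channel: str = "water") -> VolumeImage:
    """Read a station volume from a NIfTI file or a DICOM series directory.

    Spacing and origin are populated from the file header; intensities are
    returned unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        data, spacing, origin = _read_dicom_series(path)
    else:
        data, spacing, origin = _read_nifti(path)
    return VolumeImage(data=data, spacing_mm=spacing, origin_mm=origin, channel=channel)


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(image: VolumeImage, path: str | Path) -> None:
    """Write a volume as NIfTI with a lossless round-trip for its dtype."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(image.data)
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValueError(f"refusing to write non-finite values to {path}")
    img = nib.Nifti1Image(data, _affine(image.spacing_mm, image.origin_mm))
    img.header.set_zooms(image.spacing_mm)
    nib.save(img, str(path))


def read_label(path: str | Path) -> LabelVolume:
    """Read a label/probability mask from NIfTI."""
    vol = read_volume(path)
    return LabelVolume(vol.data, vol.spacing_mm, vol.origin_mm)


def write_label(label: LabelVolume, path: str | Path) -> None:
    data = label.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    write_volume(VolumeImage(data, label.spacing_mm, label.origin_mm), path)


@dataclass
class CohortManifest:
    """Rows of subject_id + station paths (+ optional truth paths, anomaly tag)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_MANIFEST_COLUMNS if c not in self.table.columns]
        if missing and len(self.table):
            raise ValueError(f"manifest missing required columns: {missing}")
        if len(self.table) and self.table["subject_id"].duplicated().any():
            dupes = self.table["subject_id"][self.table["subject_id"].duplicated()]
            raise ValueError(f"duplicate subject_id values in manifest: {list(dupes)}")

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return (row for _, row in self.table.iterrows())

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"]) if len(self.table) else []

    def save(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    An empty file yields an empty manifest (with a logged warning); duplicate
    subject ids or missing required columns are errors.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such manifest: {path}")
    try:
        table = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"manifest {path} is empty", stacklevel=2)
        log.warning("manifest %s is empty", path)
        return CohortManifest(pd.DataFrame(columns=list(_REQUIRED_MANIFEST_COLUMNS)))
    manifest = CohortManifest(table)
    if check_files:
        for col in ("station_a", "station_b", "truth_a", "truth_b"):
            if col not in table.columns:
                continue
            for p in table[col].dropna():
                if not Path(p).exists():
                    raise IOError(f"manifest references missing file: {p}")
    return manifest
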