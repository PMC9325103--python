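"""Reading and writing CT volumes, label volumes, and phantom triples.

NIfTI files store arrays in this package's native ``(slice, row, col)`` order
with the affine carrying ``(slice_spacing, row_mm, col_mm)`` on its diagonal.
DICOM series are read with pydicom: one file per coronal slice, Hounsfield
rescale applied, ``PixelSpacing`` required.
"""

from __future__ import annotations


from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .phantom import PhantomTruth
from .scheme import DEFAULT_SCHEME
from .volume import CTVolume, LabelVolume

__all__ = [
    "MetadataError",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
    "write_phantom",
    "read_phantom",
]


class MetadataError(ValueError):
    """Required imaging metadata is missing or inconsistent."""


def _affine(pixel_spacing: tuple[float, float], slice_spacing: float) -> np.ndarray:
    return np.diag([slice_spacing, pixel_spacing[0], pixel_spacing[1], 1.0])


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(vol.voxels, dtype=np.float32),
        _affine(vol.pixel_spacing, vol.slice_spacing),
    )
    nib.save(img, str(path))
    return path


def write_labels(lab: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(lab.labels, dtype=np.uint8),
        _affine(lab.pixel_spacing, lab.slice_spacing),
    )
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    slice_spacing = float(zooms[0])
    pixel_spacing = (float(zooms[1]), float(zooms[2]))
    if pixel_spacing[0] <= 0 or pixel_spacing[1] <= 0:
        raise MetadataError(f"{path}: non-positive pixel spacing {pixel_spacing}")
    return data, pixel_spacing, slice_spacing


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple[float, float], float]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise MetadataError(f"{path}: no readable DICOM files")

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)

    spacings = set()
    slices = []
    for ds in datasets:
        if not hasattr(ds, "PixelSpacing"):
            raise MetadataError(f"{path}: DICOM series missing PixelSpacing")
        spacings.add((float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])))
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    if len(spacings) != 1:
        raise MetadataError(f"{path}: mixed PixelSpacing within series: {spacings}")
    pixel_spacing = spacings.pop()

    slice_spacing = None
    positions = [
        float(ds.ImagePositionPatient[2])
        for ds in datasets
        if hasattr(ds, "ImagePositionPatient")
    ]
    if len(positions) >= 2:
        diffs = np.diff(sorted(positions))
        if diffs.size and np.all(diffs > 0):
            slice_spacing = float(np.median(diffs))
    if slice_spacing is None:
        slice_spacing = float(
            getattr(datasets[0], "SpacingBetweenSlices", 0)
            or getattr(datasets[0], "SliceThickness", 0)
            or 0
        )
    if slice_spacing <= 0:
        raise MetadataError(f"{path}: cannot determine slice spacing")

    return np.stack(slices), pixel_spacing, slice_spacing


def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory."""
    path = Path(path)
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        data, pixel_spacing, slice_spacing = _read_nifti(path)
        data = data.astype(np.float32)
    elif format == "dicom-series":
        data, pixel_spacing, slice_spacing = _read_dicom_series(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return CTVolume(
        voxels=data,
        pixel_spacing=pixel_spacing,
        slice_spacing=slice_spacing,
        source_id=path.stem if path.is_file() else path.name,
    )


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    data, pixel_spacing, slice_spacing = _read_nifti(path)
    return LabelVolume(
        labels=np.rint(data).astype(np.uint8),
        pixel_spacing=pixel_spacing,
        slice_spacing=slice_spacing,
        scheme=DEFAULT_SCHEME,
        source_id=path.stem,
    )


def write_phantom(
    out_dir: str | Path,
    stem: str,
    vol: CTVolume,
    lab: LabelVolume,
    truth: PhantomTruth,
) -> dict[str, Path]:
    """Write image/labels/truth with a shared filename stem."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}_image.nii.gz",
        "labels": out_dir / f"{stem}_labels.nii.gz",
        "truth": out_dir / f"{stem}_truth.json",
    }
    write_volume(vol, paths["image"])
    write_labels(lab, paths["labels"])
    paths["truth"].write_text(truth.to_json())
    return paths


def read_phantom(
    out_dir: str | Path, stem: str
) -> tuple[CTVolume, LabelVolume, PhantomTruth]:
    out_dir = Path(out_dir)
    vol = read_volume(out_dir / f"{stem}_image.nii.gz", "nifti")
    lab = read_labels(out_dir / f"{stem}_labels.nii.gz")
    truth = PhantomTruth.from_json(
        (out_dir / f"{stem}_truth.json").read_text()
    )
    return vol, lab, truth
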