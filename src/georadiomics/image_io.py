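"""Read/write volumes, masks, point labels and feature tables.

NRRD volumes and binary masks go through SimpleITK; DICOM CT series are read
with pydicom and converted to Hounsfield Units via the rescale slope/intercept.
All coordinates are in the volume's own axis-aligned physical frame
(``mm = origin + index * spacing``); oblique orientations are rejected.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
import SimpleITK as sitk

from .feature_table import META_COLUMNS, FeatureTable
from .image import CTVolume, ImageGrid, PointClass, PointLabel

__all__ = [
    "ImageFormatError",
    "MetadataError",
    "read_volume_nrrd",
    "write_volume_nrrd",
    "write_mask_nrrd",
    "read_dicom_series",
    "read_point_labels",
    "write_point_labels",
    "read_feature_table",
    "write_feature_table",
]

logger = logging.getLogger(__name__)

_ORIENT_TOL = 1e-6


class ImageFormatError(ValueError):
    """The file's array structure is not a 3D scalar volume."""


class MetadataError(ValueError):
    """Required geometric metadata is missing or inconsistent."""


def _grid_from_sitk(img: sitk.Image) -> ImageGrid:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=_ORIENT_TOL):
        raise MetadataError(
            "oblique/non-identity orientation is not supported; "
            f"direction matrix was {direction.tolist()}"
        )
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"non-positive spacing in header: {spacing}")
    return ImageGrid(origin=img.GetOrigin(), spacing=spacing, shape=img.GetSize())


def read_volume_nrrd(path: str | Path, patient_id: str = "") -> CTVolume:
    """Read a 3D scalar NRRD volume into a :class:`CTVolume`.

    A header without a space origin yields origin (0, 0, 0); this is logged,
    not an error, because volumes and masks are co-registered by construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise ImageFormatError(
            f"{path.name}: expected a 3D scalar array, got "
            f"{img.GetDimension()}D x {img.GetNumberOfComponentsPerPixel()} components"
        )
    grid = _grid_from_sitk(img)
    if all(abs(o) < 1e-12 for o in grid.origin):
        logger.info("%s: origin absent or zero; using (0, 0, 0)", path.name)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # [z,y,x] -> [x,y,z]
    return CTVolume(grid=grid, values=values, patient_id=patient_id or path.stem)


def _to_sitk(values: np.ndarray, grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    return img


def write_volume_nrrd(volume: CTVolume, path: str | Path) -> None:
    """Write a :class:`CTVolume` as NRRD, preserving grid geometry."""
    sitk.WriteImage(_to_sitk(volume.values, volume.grid), str(Path(path)))


def write_mask_nrrd(mask: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    """Write a boolean mask as a {0,1} uint8 NRRD on the source grid."""
    sitk.WriteImage(_to_sitk(mask.astype(np.uint8), grid), str(Path(path)))


def read_dicom_series(directory: str | Path, patient_id: str = "") -> CTVolume:
    """Read one axial CT series from a directory and convert to HU.

    Slices are sorted by physical z-position; values are
    ``raw * RescaleSlope + RescaleIntercept``.  Mixed series UIDs and
    non-uniform slice spacing (beyond 0.01 mm) are errors.
    """
    directory = Path(directory)
    slices = []
    for f in sorted(directory.iterdir()):
        if f.is_file():
            try:
                ds = pydicom.dcmread(str(f))
            except Exception:
                continue
            if hasattr(ds, "PixelData"):
                slices.append(ds)
    if not slices:
        raise ImageFormatError(f"{directory}: no readable DICOM image slices")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in slices}
    if len(uids) > 1:
        raise MetadataError(f"{directory}: multiple series in one directory: {sorted(uids)}")

    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=_ORIENT_TOL):
        raise MetadataError(f"non-axial slice orientation not supported: {orient.tolist()}")

    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if np.ptp(dz) > 1e-2:
            gaps = [(i, float(d)) for i, d in enumerate(dz)]
            raise MetadataError(f"non-uniform slice spacing; per-gap dz (index, mm): {gaps}")
        slice_spacing = float(np.mean(dz))
    else:
        slice_spacing = float(getattr(slices[0], "SliceThickness", 1.0))

    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)  # (y, x)
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)

    hu_slices = []
    for ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu_slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    stack = np.stack(hu_slices, axis=0)  # [z, row(y), col(x)]
    values = stack.transpose(2, 1, 0)  # -> [x, y, z]

    grid = ImageGrid(origin=origin, spacing=(col_sp, row_sp, slice_spacing), shape=values.shape)
    pid = patient_id or str(getattr(slices[0], "PatientID", directory.name))
    return CTVolume(grid=grid, values=values, patient_id=pid)


_LABEL_COLUMNS = ["patient_id", "x_mm", "y_mm", "z_mm", "label"]


def read_point_labels(path: str | Path) -> list[PointLabel]:
    """Read center-point labels from CSV (canonical) or JSON.

    Labels are matched case-insensitively against {BM, HB} and normalized.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame.from_records(records)
        if records == []:
            df = pd.DataFrame(columns=_LABEL_COLUMNS)
    else:
        df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path.name}: missing columns {missing}")

    points = []
    for i, row in df.iterrows():
        raw = str(row["label"]).strip().upper()
        if raw not in (PointClass.BM.value, PointClass.HB.value):
            raise ValueError(
                f"{path.name} row {i}: unknown label {row['label']!r} (expected BM or HB)"
            )
        points.append(
            PointLabel(
                patient_id=str(row["patient_id"]),
                position=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                label=PointClass(raw),
                annotator=str(row["annotator"]) if "annotator" in df.columns else None,
                point_id=str(row["point_id"]) if "point_id" in df.columns else str(i),
            )
        )
    return points


def write_point_labels(points: list[PointLabel], path: str | Path) -> None:
    """Write point labels as canonical five-column CSV (plus point_id)."""
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in points],
            "x_mm": [p.position[0] for p in points],
            "y_mm": [p.position[1] for p in points],
            "z_mm": [p.position[2] for p in points],
            "label": [p.label.value for p in points],
            "point_id": [p.point_id for p in points],
        }
    )
    df.to_csv(path, index=False)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV, lossless to float64 precision."""
    n_nan = int(table.data[table.feature_names].isna().to_numpy().sum())
    if n_nan:
        logger.warning("feature table has %d missing cells; written as empty fields", n_nan)
    table.data.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    # pandas silently mangles duplicate column names, so check the raw header
    with open(path) as fh:
        header = next(csv.reader(fh))
    dupes = sorted({n for n in header if header.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate feature columns in {path}: {dupes}")
    df = pd.read_csv(path, dtype={c: str for c in META_COLUMNS if c != "label"})
    names = [c for c in header if c not in META_COLUMNS]
    n_nan = int(df[names].isna().to_numpy().sum())
    if n_nan:
        logger.warning("%s: %d missing feature cells", path, n_nan)
    return FeatureTable(df)
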