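"""CT volume containers, DICOM series I/O and Hounsfield-unit conversion.

Scanner exports store integer pixel values together with a linear rescale
(slope, intercept) in the image header; all quantification in this package
runs on the rescaled Hounsfield-unit (HU) grid.  Conventions fixed here and
used everywhere else:

* array index order is ``(slice, row, column)``, 0-based;
* voxel spacing is a 3-tuple of micrometres in the same axis order;
* ``HU = stored_pixels * rescale_slope + rescale_intercept``, elementwise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, InputError, MetadataError

__all__ = [
    "CTVolume",
    "HUVolume",
    "to_hounsfield",
    "from_hounsfield",
    "read_dicom_series",
    "write_dicom_series",
    "read_raw_volume",
    "write_raw_volume",
]

log = logging.getLogger(__name__)


@dataclass
class CTVolume:
    """A raw scanner-side volume: stored integer pixels plus rescale metadata.

    Parameters
    ----------
    stored_pixels
        3D integer array, index order ``(slice, row, column)``.
    rescale_slope, rescale_intercept
        Linear map from stored pixel values to Hounsfield units.
    voxel_size
        Spacing in micrometres per axis, ``(slice, row, column)``.
    sample_id
        Free-text identifier carried through the pipeline.
    """

    stored_pixels: np.ndarray
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    voxel_size: tuple[float, float, float] = (6.0, 6.0, 6.0)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.stored_pixels = np.asarray(self.stored_pixels)
        if self.stored_pixels.ndim != 3 or self.stored_pixels.size == 0:
            raise InputError("stored_pixels must be a non-empty 3D array")
        if not np.issubdtype(self.stored_pixels.dtype, np.integer):
            raise InputError("stored_pixels must have an integer dtype")
        if self.rescale_slope == 0:
            raise MetadataError("rescale_slope must be nonzero")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InputError("voxel_size must be three positive micrometre spacings")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stored_pixels.shape


@dataclass
class HUVolume:
    """A volume on the Hounsfield-unit scale; all quantification consumes this."""

    hu: np.ndarray
    voxel_size: tuple[float, float, float] = (6.0, 6.0, 6.0)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        if self.hu.ndim != 3 or self.hu.size == 0:
            raise InputError("hu must be a non-empty 3D array")
        if not np.isfinite(self.hu).all():
            raise InputError("hu must contain only finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InputError("voxel_size must be three positive micrometre spacings")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape


def to_hounsfield(vol: CTVolume) -> HUVolume:
    """Convert stored pixel values to Hounsfield units using the rescale metadata.

    ``hu = stored_pixels * rescale_slope + rescale_intercept`` elementwise;
    shape and spacing are preserved.
    """
    if vol.rescale_slope == 0:
        raise MetadataError("rescale_slope must be nonzero")
    hu = vol.stored_pixels.astype(np.float64) * vol.rescale_slope + vol.rescale_intercept
    return HUVolume(hu=hu, voxel_size=vol.voxel_size, sample_id=vol.sample_id)


def from_hounsfield(hu: HUVolume, rescale_slope: float, rescale_intercept: float) -> np.ndarray:
    """Invert the affine HU transform, returning real-valued stored pixels (no rounding)."""
    if rescale_slope == 0:
        raise MetadataError("rescale_slope must be nonzero")
    return (hu.hu - rescale_intercept) / rescale_slope


# ---------------------------------------------------------------------------
# DICOM series I/O
# ---------------------------------------------------------------------------

def _slice_sort_key(ds: pydicom.Dataset, index: int):
    pos = getattr(ds, "ImagePositionPatient", None)
    if pos is not None and len(pos) == 3:
        return (0, float(pos[2]))
    inst = getattr(ds, "InstanceNumber", None)
    if inst is not None:
        return (1, float(inst))
    return (2, float(index))


def read_dicom_series(path: str | Path) -> CTVolume:
    """Read a directory of single-frame CT slices into a :class:`CTVolume`.

    Slices are stacked in ascending slice-position order (fallback: instance
    number), so the result is invariant to on-disk file naming and order.
    Missing rescale fields default to slope 1, intercept 0 with a warning.
    """
    path = Path(path)
    if not path.is_dir():
        raise InputError(f"not a directory: {path}")
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(p))
        except Exception:  # non-DICOM files (manifests etc.) are skipped
            continue
    if not datasets:
        raise InputError(f"no DICOM slices found in {path}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice shapes in series: {sorted(shapes)}")

    return _stack_series(datasets)


def _stack_series(datasets: list[pydicom.Dataset]) -> CTVolume:
    order = sorted(range(len(datasets)), key=lambda i: _slice_sort_key(datasets[i], i))
    datasets = [datasets[i] for i in order]
    first = datasets[0]

    slope = getattr(first, "RescaleSlope", None)
    intercept = getattr(first, "RescaleIntercept", None)
    if slope is None or intercept is None:
        warnings.warn(
            "RescaleSlope/RescaleIntercept missing; defaulting to slope=1, intercept=0",
            stacklevel=3,
        )
        slope = 1.0 if slope is None else slope
        intercept = 0.0 if intercept is None else intercept

    # PixelSpacing is (row, column) in mm; internal geometry is micrometres.
    ps = getattr(first, "PixelSpacing", [0.006, 0.006])
    row_um, col_um = float(ps[0]) * 1000.0, float(ps[1]) * 1000.0
    slice_um = None
    if len(datasets) > 1:
        try:
            z0 = float(datasets[0].ImagePositionPatient[2])
            z1 = float(datasets[1].ImagePositionPatient[2])
            slice_um = abs(z1 - z0) * 1000.0
        except Exception:
            slice_um = None
    if not slice_um:
        slice_um = float(getattr(first, "SliceThickness", 0.006)) * 1000.0

    pixels = np.stack([ds.pixel_array for ds in datasets], axis=0)
    return CTVolume(
        stored_pixels=pixels,
        rescale_slope=float(slope),
        rescale_intercept=float(intercept),
        voxel_size=(slice_um, row_um, col_um),
        sample_id=str(getattr(first, "PatientID", "")),
    )


def write_dicom_series(vol: CTVolume, path: str | Path) -> list[Path]:
    """Write a :class:`CTVolume` as one single-frame CT DICOM file per slice.

    RescaleSlope/RescaleIntercept, PixelSpacing, SliceThickness and slice
    positions are populated so that :func:`read_dicom_series` round-trips.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pixels = vol.stored_pixels
    if pixels.min() < 0 or pixels.max() > np.iinfo(np.uint16).max:
        raise InputError("stored pixels must fit an unsigned 16-bit range for DICOM export")
    pixels = pixels.astype(np.uint16)

    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    slice_mm = vol.voxel_size[0] / 1000.0
    written: list[Path] = []
    for k in range(pixels.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientID = vol.sample_id or "PHANTOM"
        ds.PatientName = vol.sample_id or "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, round(k * slice_mm, 9)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = slice_mm
        ds.PixelSpacing = [vol.voxel_size[1] / 1000.0, vol.voxel_size[2] / 1000.0]
        ds.RescaleSlope = vol.rescale_slope
        ds.RescaleIntercept = vol.rescale_intercept
        ds.Rows, ds.Columns = pixels.shape[1], pixels.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0  # unsigned
        ds.PixelData = pixels[k].tobytes()

        out = path / f"slice_{k:04d}.dcm"
        ds.save_as(out, enforce_file_format=True)
        written.append(out)
    return written


# ---------------------------------------------------------------------------
# Raw volume + JSON sidecar (lightweight fallback container)
# ---------------------------------------------------------------------------

def write_raw_volume(vol: CTVolume, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``<basepath>.raw`` (little-endian uint16) plus ``<basepath>.json`` sidecar."""
    basepath = Path(basepath)
    raw_path = basepath.with_suffix(".raw")
    json_path = basepath.with_suffix(".json")
    pixels = vol.stored_pixels.astype("<u2")
    raw_path.write_bytes(pixels.tobytes())
    sidecar = {
        "shape": list(vol.shape),
        "dtype": "<u2",
        "rescale_slope": vol.rescale_slope,
        "rescale_intercept": vol.rescale_intercept,
        "voxel_size_um": list(vol.voxel_size),
        "sample_id": vol.sample_id,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return raw_path, json_path


def read_raw_volume(basepath: str | Path) -> CTVolume:
    """Read a volume written by :func:`write_raw_volume`."""
    basepath = Path(basepath)
    raw_path = basepath.with_suffix(".raw")
    json_path = basepath.with_suffix(".json")
    if not raw_path.exists() or not json_path.exists():
        raise InputError(f"missing raw volume or sidecar at {basepath}")
    sidecar = json.loads(json_path.read_text())
    shape = tuple(sidecar["shape"])
    pixels = np.frombuffer(raw_path.read_bytes(), dtype=sidecar["dtype"]).reshape(shape)
    return CTVolume(
        stored_pixels=pixels.astype(np.uint16),
        rescale_slope=float(sidecar["rescale_slope"]),
        rescale_intercept=float(sidecar["rescale_intercept"]),
        voxel_size=tuple(sidecar["voxel_size_um"]),
        sample_id=sidecar.get("sample_id", ""),
    )
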