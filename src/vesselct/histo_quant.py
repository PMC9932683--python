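"""Collagen content from picrosirius-red histology with dual polarized-light images.

A section stained with picrosirius red is imaged in brightfield (tissue
outline) and twice under crossed polarizers, 90° apart, so that birefringent
collagen extinguished at one analyser angle is bright at the other.  The two
polarized-light (PLM) images are combined pixelwise, both the combined PLM
image and the brightfield image are binarized, and the collagen content of an
ROI is

    content = (# white PLM pixels in ROI ∩ tissue) / (# white brightfield pixels in ROI)

which lives in [0, 1] because the numerator is restricted to tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, InputError, MeasurementError

__all__ = [
    "HistologyTriplet",
    "CollagenMeasurement",
    "combine_plm",
    "binarize",
    "collagen_content",
    "read_triplet",
    "write_triplet",
    "disc_mask",
    "rect_mask",
]


@dataclass
class HistologyTriplet:
    """One registered brightfield + dual-PLM image set of a single section.

    All three images share a shape; white-on-dark polarity is assumed
    (tissue and birefringent collagen are bright).  ``pixel_size`` is in
    micrometres.
    """

    brightfield: np.ndarray
    plm_0: np.ndarray
    plm_90: np.ndarray
    pixel_size: float = 1.0
    sample_id: str = ""
    section_id: str = ""

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield)
        self.plm_0 = np.asarray(self.plm_0)
        self.plm_90 = np.asarray(self.plm_90)
        shapes = {self.brightfield.shape, self.plm_0.shape, self.plm_90.shape}
        if len(shapes) != 1:
            raise InputError(f"triplet images must share a shape, got {shapes}")
        if self.brightfield.ndim != 2:
            raise InputError("triplet images must be 2D grayscale")
        if self.pixel_size <= 0:
            raise InputError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape


@dataclass(frozen=True)
class CollagenMeasurement:
    """The collagen-content statistic for one section/ROI, with raw counts."""

    sample_id: str
    section_id: str
    roi: str
    collagen_content: float
    n_tissue_pixels: int
    n_collagen_pixels: int


def combine_plm(plm_0: np.ndarray, plm_90: np.ndarray) -> np.ndarray:
    """Combine the two crossed-polarizer images by pixelwise maximum.

    A fibre extinguished at one analyser angle is bright at the other, so
    keeping the brighter of the two values recovers all birefringent signal
    without the overflow that addition would cause.
    """
    plm_0 = np.asarray(plm_0)
    plm_90 = np.asarray(plm_90)
    if plm_0.shape != plm_90.shape:
        raise InputError(f"PLM image shapes differ: {plm_0.shape} vs {plm_90.shape}")
    return np.maximum(plm_0, plm_90)


def binarize(image: np.ndarray, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binarize a grayscale image; white (True) is foreground.

    ``method="otsu"`` picks the threshold maximizing between-class variance
    of the intensity histogram and marks pixels strictly above it white.
    ``method="fixed"`` marks pixels with intensity >= ``threshold`` white.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InputError("cannot binarize an empty image")
    if method == "otsu":
        if image.min() == image.max():
            raise DegenerateImageError(
                "image is constant; Otsu thresholding is undefined — use method='fixed'"
            )
        return image > threshold_otsu(image)
    if method == "fixed":
        if threshold is None:
            raise InputError("method='fixed' requires a threshold")
        return image >= threshold
    raise InputError(f"unknown binarization method {method!r}")


def collagen_content(
    triplet: HistologyTriplet,
    roi: np.ndarray | None = None,
    method: str = "otsu",
    threshold: float | None = None,
    roi_name: str = "full",
) -> CollagenMeasurement:
    """Compute the collagen-content statistic for an ROI of a triplet.

    The combined PLM image and the brightfield image are binarized with the
    same method; collagen pixels outside the brightfield tissue mask are
    excluded from the numerator, so the ratio is always in [0, 1].  An
    all-dark combined PLM image under Otsu is treated as zero collagen.
    """
    if roi is None:
        roi = np.ones(triplet.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != triplet.shape:
        raise InputError(f"ROI shape {roi.shape} does not match images {triplet.shape}")

    combined = combine_plm(triplet.plm_0, triplet.plm_90)
    try:
        plm_mask = binarize(combined, method=method, threshold=threshold)
    except DegenerateImageError:
        if combined.max() == 0:
            plm_mask = np.zeros(triplet.shape, dtype=bool)  # no birefringent signal at all
        else:
            raise
    tissue_mask = binarize(triplet.brightfield, method=method, threshold=threshold)

    n_tissue = int((tissue_mask & roi).sum())
    if n_tissue == 0:
        raise MeasurementError("ROI contains no tissue pixels; collagen content is undefined")
    n_collagen = int((plm_mask & tissue_mask & roi).sum())
    return CollagenMeasurement(
        sample_id=triplet.sample_id,
        section_id=triplet.section_id,
        roi=roi_name,
        collagen_content=n_collagen / n_tissue,
        n_tissue_pixels=n_tissue,
        n_collagen_pixels=n_collagen,
    )


# ---------------------------------------------------------------------------
# ROI mask helpers
# ---------------------------------------------------------------------------

def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disc: pixel centers strictly closer than ``radius`` to ``center``."""
    rr, cc = np.ogrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2


def rect_mask(shape: tuple[int, int], r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    """Boolean rectangle over rows [r0, r1) and columns [c0, c1)."""
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


# ---------------------------------------------------------------------------
# Manifest-based I/O
# ---------------------------------------------------------------------------

def write_triplet(triplet: HistologyTriplet, path: str | Path, fmt: str = "png") -> Path:
    """Write the three images plus a JSON manifest naming them; returns the manifest path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = {}
    for key, img in (
        ("brightfield", triplet.brightfield),
        ("plm_0", triplet.plm_0),
        ("plm_90", triplet.plm_90),
    ):
        fname = f"{key}.{fmt}"
        iio.imwrite(path / fname, np.asarray(img, dtype=np.uint8))
        names[key] = fname
    manifest = {
        **names,
        "pixel_size_um": triplet.pixel_size,
        "invert_brightfield": False,
        "sample_id": triplet.sample_id,
        "section_id": triplet.section_id,
    }
    manifest_path = path / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_triplet(manifest_path: str | Path) -> HistologyTriplet:
    """Read a triplet via its JSON manifest.

    ``invert_brightfield: true`` flips a dark-tissue-on-bright-background
    brightfield image so the white-on-dark convention holds downstream.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent

    def _load(key: str) -> np.ndarray:
        img = iio.imread(base / manifest[key])
        if img.ndim == 3:  # collapse RGB(A) to grayscale by channel mean
            img = img[..., :3].mean(axis=-1).astype(img.dtype)
        return img

    brightfield = _load("brightfield")
    if manifest.get("invert_brightfield", False):
        info_max = np.iinfo(brightfield.dtype).max if np.issubdtype(brightfield.dtype, np.integer) else brightfield.max()
        brightfield = info_max - brightfield
    return HistologyTriplet(
        brightfield=brightfield,
        plm_0=_load("plm_0"),
        plm_90=_load("plm_90"),
        pixel_size=float(manifest.get("pixel_size_um", 1.0)),
        sample_id=manifest.get("sample_id", ""),
        section_id=manifest.get("section_id", ""),
    )
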