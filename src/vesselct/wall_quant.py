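"""Media ROI measurements, line profiles and the display window/level transform.

The study protocol measures mean HU in three circular ROIs in the internal
media and three in the external media, on each of three slices, and averages
the nine ROI means per region.  "Internal" and "external" media are
operationalized here as the inner and outer radial thirds of the media band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .ct_io import HUVolume
from .errors import InputError, PlacementError, ProtocolError
from .segmentation import Layer, LayerLabelVolume

__all__ = [
    "ROISpec",
    "RoiMeasurement",
    "LineProfile",
    "roi_mean_hu",
    "media_roi_panel",
    "auto_place_media_rois",
    "line_profile",
    "window_level",
]

INTERNAL = "internal_media"
EXTERNAL = "external_media"


@dataclass(frozen=True)
class ROISpec:
    """A circular ROI on one slice: pixel centers strictly inside ``radius``
    of ``center`` (row, column) belong to the disc."""

    slice_index: int
    center: tuple[float, float]
    radius: float
    region_tag: str = INTERNAL

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise InputError("ROI radius must be >= 1 pixel")


def _disc_pixels(roi: ROISpec, slice_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    cr, cc = roi.center
    n_rows, n_cols = slice_shape
    if cr - roi.radius < 0 or cr + roi.radius > n_rows - 1 or cc - roi.radius < 0 or cc + roi.radius > n_cols - 1:
        raise InputError(f"ROI at {roi.center} radius {roi.radius} extends outside the slice")
    r0, r1 = int(np.floor(cr - roi.radius)), int(np.ceil(cr + roi.radius)) + 1
    c0, c1 = int(np.floor(cc - roi.radius)), int(np.ceil(cc + roi.radius)) + 1
    rr, cc_idx = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = (rr - cr) ** 2 + (cc_idx - cc) ** 2 < roi.radius**2
    return rr[inside], cc_idx[inside]


def roi_mean_hu(hu: HUVolume, roi: ROISpec) -> float:
    """Arithmetic mean HU over the disc's pixel-center-inside set."""
    if not 0 <= roi.slice_index < hu.shape[0]:
        raise InputError(f"slice_index {roi.slice_index} outside volume")
    rows, cols = _disc_pixels(roi, hu.shape[1:])
    return float(hu.hu[roi.slice_index, rows, cols].mean())


@dataclass
class RoiMeasurement:
    """Per-region summary: raw per-ROI means plus their grand mean.

    ``roi_means`` holds ``(slice_index, roi_index_on_slice, mean_hu, n_voxels)``
    for audit; the grand mean is the unweighted mean of the ROI means.
    """

    sample_id: str
    region_tag: str
    roi_means: list[tuple[int, int, float, int]] = field(default_factory=list)
    grand_mean_hu: float = float("nan")
    n_voxels: int = 0


def media_roi_panel(
    hu: HUVolume,
    rois: Sequence[ROISpec],
    n_slices: int = 3,
    n_per_region: int = 3,
    sample_id: str = "",
) -> tuple[RoiMeasurement, RoiMeasurement]:
    """Measure the internal/external media ROI panel.

    Requires ``n_per_region`` ROIs per region on each of ``n_slices`` distinct
    slices (default 3+3 ROIs × 3 slices); the grand mean per region averages
    the per-ROI means.  Raises :class:`ProtocolError` listing what is missing.
    """
    by_region: dict[str, dict[int, list[ROISpec]]] = {INTERNAL: {}, EXTERNAL: {}}
    for roi in rois:
        if roi.region_tag not in by_region:
            raise ProtocolError(f"unknown region tag {roi.region_tag!r}")
        by_region[roi.region_tag].setdefault(roi.slice_index, []).append(roi)

    problems = []
    for tag, per_slice in by_region.items():
        if len(per_slice) != n_slices:
            problems.append(f"{tag}: expected {n_slices} distinct slices, got {len(per_slice)}")
        for s, lst in sorted(per_slice.items()):
            if len(lst) != n_per_region:
                problems.append(f"{tag} slice {s}: expected {n_per_region} ROIs, got {len(lst)}")
    if problems:
        raise ProtocolError("ROI protocol incomplete: " + "; ".join(problems))

    out = []
    for tag in (INTERNAL, EXTERNAL):
        meas = RoiMeasurement(sample_id=sample_id, region_tag=tag)
        means = []
        for s in sorted(by_region[tag]):
            for j, roi in enumerate(by_region[tag][s]):
                rows, cols = _disc_pixels(roi, hu.shape[1:])
                vals = hu.hu[roi.slice_index, rows, cols]
                meas.roi_means.append((s, j, float(vals.mean()), int(vals.size)))
                meas.n_voxels += int(vals.size)
                means.append(vals.mean())
        meas.grand_mean_hu = float(np.mean(means))
        out.append(meas)
    return out[0], out[1]


def auto_place_media_rois(
    labels: LayerLabelVolume,
    slices: Sequence[int],
    n_per_region: int = 3,
    radius: float = 3.0,
    seed: int = 0,
) -> list[ROISpec]:
    """Place internal/external media ROIs automatically on the given slices.

    Internal ROIs are centered in the inner third of the media's radial band,
    external ROIs in the outer third, spread in angle with a seeded common
    offset.  Every disc is required to lie entirely on media-labelled pixels;
    if no admissible position exists near a target angle a
    :class:`PlacementError` suggests a smaller radius.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    rois: list[ROISpec] = []
    for s in slices:
        if not 0 <= s < labels.shape[0]:
            raise InputError(f"slice index {s} outside volume")
        media = labels.labels[s] == int(Layer.MEDIA)
        if not media.any():
            raise PlacementError(f"no media pixels on slice {s}")
        # opening drops speckle from noise-flipped voxels, then keep the
        # largest connected component: partial-volume rings at other
        # interfaces can alias into the media HU interval but are detached
        # from the true media annulus
        opened = ndimage.binary_opening(media, structure=np.ones((3, 3), dtype=bool))
        if opened.any():
            media = opened
        comp, n_comp = ndimage.label(media, structure=np.ones((3, 3), dtype=bool))
        if n_comp > 1:
            sizes = ndimage.sum_labels(media, comp, index=np.arange(1, n_comp + 1))
            media = comp == (1 + int(np.argmax(sizes)))
        rows, cols = np.nonzero(media)
        cr, cc = rows.mean(), cols.mean()
        radial = np.hypot(rows - cr, cols - cc)
        # percentile band bounds resist stray mislabelled voxels (noise,
        # partial-volume rings at other interfaces)
        r_in, r_out = np.percentile(radial, [1.0, 99.0])
        third = (r_out - r_in) / 3.0
        mid = (r_in + r_out) / 2.0
        targets = {
            INTERNAL: r_in + third / 2.0,
            EXTERNAL: r_out - third / 2.0,
        }
        for tag, r_target in targets.items():
            inward = 1.0 if r_target < mid else -1.0  # radial nudges move toward the band centre
            for k in range(n_per_region):
                base_angle = offset + 2.0 * np.pi * k / n_per_region
                placed = False
                for attempt in range(72):
                    # search outward in angle from the target position
                    delta = ((attempt + 1) // 2) * 0.0873 * (1 if attempt % 2 else -1)
                    angle = base_angle + delta
                    for r_nudge in (0.0, inward, 2.0 * inward):
                        r_try = r_target + r_nudge
                        center = (cr + r_try * np.sin(angle), cc + r_try * np.cos(angle))
                        try:
                            pr, pc = _disc_pixels(
                                ROISpec(s, center, radius, tag), labels.shape[1:]
                            )
                        except InputError:
                            continue
                        if media[pr, pc].all():
                            rois.append(ROISpec(s, center, radius, tag))
                            placed = True
                            break
                    if placed:
                        break
                if not placed:
                    raise PlacementError(
                        f"could not place a radius-{radius} {tag} ROI on slice {s}; "
                        "the media band is too thin — try a smaller radius"
                    )
    return rois


@dataclass
class LineProfile:
    """HU sampled along a line segment: positions (µm from the start) and values."""

    positions_um: np.ndarray
    hu: np.ndarray

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=np.float64)
        self.hu = np.asarray(self.hu, dtype=np.float64)
        if self.positions_um.shape != self.hu.shape:
            raise InputError("positions and values must align")
        if np.any(np.diff(self.positions_um) <= 0):
            raise InputError("positions must be strictly increasing")


def line_profile(
    hu: HUVolume,
    slice_index: int,
    start: tuple[float, float],
    end: tuple[float, float],
    n_samples: int = 100,
) -> LineProfile:
    """Sample HU at ``n_samples`` equally spaced points between two in-slice
    points, by bilinear interpolation; positions are physical (µm)."""
    if not 0 <= slice_index < hu.shape[0]:
        raise InputError(f"slice_index {slice_index} outside volume")
    if n_samples < 2:
        raise InputError("n_samples must be >= 2")
    n_rows, n_cols = hu.shape[1:]
    for name, (r, c) in (("start", start), ("end", end)):
        if not (0 <= r <= n_rows - 1 and 0 <= c <= n_cols - 1):
            raise InputError(f"{name} point {(r, c)} outside slice")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = start[0] + t * (end[0] - start[0])
    cols = start[1] + t * (end[1] - start[1])
    values = ndimage.map_coordinates(
        hu.hu[slice_index], np.vstack([rows, cols]), order=1, mode="nearest"
    )
    length_um = np.hypot(
        (end[0] - start[0]) * hu.voxel_size[1], (end[1] - start[1]) * hu.voxel_size[2]
    )
    return LineProfile(positions_um=t * length_um, hu=values)


def window_level(hu: HUVolume, level: float, width: float) -> np.ndarray:
    """Map HU to 8-bit display values with a window/level transform.

    ``d = clamp((hu - (level - width/2)) / width, 0, 1) * 255`` rounded
    half-up, so ``hu == level`` maps to 128 and values outside the window
    clamp to 0 / 255.  Display mapping only — never used for quantification.
    """
    if width <= 0:
        raise InputError("window width must be positive")
    x = np.clip((hu.hu - (level - width / 2.0)) / width, 0.0, 1.0)
    return np.floor(x * 255.0 + 0.5).astype(np.uint8)
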