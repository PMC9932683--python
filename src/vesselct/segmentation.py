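"""HU-threshold layer segmentation, seeded region growing and layer volumes.

The arterial wall is partitioned into lumen, intima, media and adventitia by
assigning each voxel the layer whose half-open HU interval ``[low, high)``
contains it.  Because the lumen and the surrounding bath are both filled with
ethanol they share an HU interval; :func:`segment_vessel` separates them with
seeded region growing, mirroring the grow-region workflow of clinical DICOM
viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .ct_io import HUVolume
from .errors import ConfigurationError, InputError, SeedError

__all__ = [
    "Layer",
    "TISSUE_LAYERS",
    "LayerThresholds",
    "LayerLabelVolume",
    "SeedPoint",
    "classify_by_threshold",
    "grow_region",
    "split_lumen_background",
    "segment_vessel",
    "majority_filter",
    "layer_volumes",
    "tissue_volume_mm3",
    "dice",
    "default_thresholds",
]


class Layer(IntEnum):
    """Voxel classes of a segmented vessel volume."""

    BACKGROUND = 0
    LUMEN = 1
    INTIMA = 2
    MEDIA = 3
    ADVENTITIA = 4


#: Layers that count toward tissue volume (wall layers, not lumen/bath).
TISSUE_LAYERS = (Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA)

#: Overlap priority, least to most dominant: the denser stain wins.
DEFAULT_PRIORITY = (Layer.LUMEN, Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA)


@dataclass(frozen=True)
class LayerThresholds:
    """Per-layer half-open HU intervals ``layer -> [low, high)``.

    A voxel falling in no interval is background.  A shared boundary value
    belongs to the interval whose ``low`` equals it (half-open convention);
    genuinely overlapping intervals are resolved by a priority order,
    adventitia > media > intima > lumen by default.
    """

    intervals: Mapping[Layer, tuple[float, float]]

    def __post_init__(self) -> None:
        seen = set()
        for layer, (low, high) in self.intervals.items():
            layer = Layer(layer)
            if layer is Layer.BACKGROUND:
                raise ConfigurationError("background has no interval; it is the complement")
            if layer in seen:
                raise ConfigurationError(f"duplicate interval for layer {layer.name}")
            seen.add(layer)
            if not low < high:
                raise ConfigurationError(
                    f"interval for {layer.name} must satisfy low < high, got ({low}, {high})"
                )
        object.__setattr__(
            self,
            "intervals",
            {Layer(k): (float(v[0]), float(v[1])) for k, v in self.intervals.items()},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LayerThresholds":
        cfg = json.loads(Path(path).read_text())
        intervals = {
            Layer[name.upper()]: tuple(bounds)
            for name, bounds in cfg["intervals"].items()
        }
        return cls(intervals=intervals)

    def to_json(self, path: str | Path) -> None:
        cfg = {"intervals": {layer.name.lower(): list(b) for layer, b in self.intervals.items()}}
        Path(path).write_text(json.dumps(cfg, indent=2))


@dataclass
class LayerLabelVolume:
    """Per-voxel categorical labels over the :class:`Layer` enumeration."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (6.0, 6.0, 6.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise InputError("labels must be a non-empty 3D array")
        valid = {int(v) for v in Layer}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise InputError(f"unknown label values: {sorted(present - valid)}")
        self.labels = self.labels.astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, layer: Layer) -> np.ndarray:
        return self.labels == int(layer)


@dataclass(frozen=True)
class SeedPoint:
    """A voxel index ``(slice, row, column)`` with its intended layer."""

    index: tuple[int, int, int]
    layer: Layer = Layer.LUMEN

    def validate(self, shape: tuple[int, int, int]) -> None:
        if len(self.index) != 3 or any(
            not (0 <= i < n) for i, n in zip(self.index, shape)
        ):
            raise SeedError(f"seed index {self.index} outside volume of shape {shape}")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise InputError(f"connectivity must be 6 or 26, got {connectivity}")


def classify_by_threshold(
    hu: HUVolume,
    thresholds: LayerThresholds,
    priority: Iterable[Layer] = DEFAULT_PRIORITY,
) -> LayerLabelVolume:
    """Assign each voxel the layer whose HU interval contains it.

    Intervals are half-open ``[low, high)``; voxels in no interval become
    background; overlaps are resolved by ``priority`` (later entries win).
    """
    labels = np.zeros(hu.shape, dtype=np.uint8)
    for layer in priority:
        if layer not in thresholds.intervals:
            continue
        low, high = thresholds.intervals[layer]
        labels[(hu.hu >= low) & (hu.hu < high)] = int(layer)
    return LayerLabelVolume(labels=labels, voxel_size=hu.voxel_size)


def grow_region(
    hu: HUVolume,
    seed: SeedPoint,
    interval: tuple[float, float],
    connectivity: int = 6,
) -> np.ndarray:
    """Seeded region growing: the connected in-interval component containing the seed.

    Membership is the half-open test ``low <= HU < high``; connectivity is
    6 (faces) or 26 (faces+edges+corners).  Returns a boolean mask.
    """
    seed.validate(hu.shape)
    low, high = interval
    seed_hu = hu.hu[seed.index]
    if not (low <= seed_hu < high):
        raise SeedError(
            f"seed HU {seed_hu:.1f} at {seed.index} outside interval [{low}, {high})"
        )
    in_interval = (hu.hu >= low) & (hu.hu < high)
    comp, _ = ndimage.label(in_interval, structure=_structure(connectivity))
    return comp == comp[seed.index]


def split_lumen_background(
    labels: LayerLabelVolume,
    seed: SeedPoint | None = None,
    connectivity: int = 6,
    snap_radius: int = 5,
) -> LayerLabelVolume:
    """Separate the lumen from the bath among ethanol-labelled voxels.

    Threshold classification cannot tell the lumen from the surrounding
    ethanol bath (identical HU); only the connected component containing the
    lumen seed keeps the lumen label, the rest becomes background.  The
    default seed is the volume centre.  If the seed voxel itself is not in
    the candidate class (a noise flip), it snaps to the nearest candidate
    within ``snap_radius`` voxels; ``snap_radius=0`` makes the seed strict.
    """
    if seed is None:
        seed = SeedPoint(tuple(n // 2 for n in labels.shape), Layer.LUMEN)
    seed.validate(labels.shape)
    lumen_like = labels.mask(Layer.LUMEN)
    seed_index = seed.index
    if not lumen_like[seed_index]:
        seed_index = _snap_to_mask(lumen_like, seed.index, snap_radius)
        if seed_index is None:
            raise SeedError(f"seed {seed.index} is not in the lumen-candidate class")
    comp, _ = ndimage.label(lumen_like, structure=_structure(connectivity))
    out = labels.labels.copy()
    out[lumen_like & (comp != comp[seed_index])] = int(Layer.BACKGROUND)
    return LayerLabelVolume(labels=out, voxel_size=labels.voxel_size)


def _snap_to_mask(
    mask: np.ndarray, index: tuple[int, int, int], radius: int
) -> tuple[int, int, int] | None:
    """Nearest True voxel to ``index`` within a cubic search ball, or None."""
    if radius <= 0:
        return None
    lo = [max(0, i - radius) for i in index]
    hi = [min(n, i + radius + 1) for i, n in zip(index, mask.shape)]
    sub = mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    cand = np.argwhere(sub)
    if len(cand) == 0:
        return None
    origin = np.array(index) - np.array(lo)
    best = cand[np.argmin(((cand - origin) ** 2).sum(axis=1))]
    return tuple(int(v) for v in best + np.array(lo))


def majority_filter(labels: LayerLabelVolume, size: int = 3) -> LayerLabelVolume:
    """Replace each voxel by the majority label in its ``size``³ neighbourhood.

    Optional cleanup for noisy classifications; ties go to the lowest label
    value for determinism.
    """
    values = np.array(sorted({int(v) for v in np.unique(labels.labels)}), dtype=np.uint8)
    counts = np.stack(
        [ndimage.uniform_filter((labels.labels == v).astype(np.float32), size=size) for v in values]
    )
    out = values[np.argmax(counts, axis=0)]
    return LayerLabelVolume(labels=out, voxel_size=labels.voxel_size)


def segment_vessel(
    hu: HUVolume,
    thresholds: LayerThresholds,
    lumen_seed: SeedPoint | None = None,
    connectivity: int = 6,
    majority: bool = False,
) -> LayerLabelVolume:
    """Full vessel segmentation: threshold classification, optional majority
    cleanup, then lumen/bath separation by seeded region growing."""
    labels = classify_by_threshold(hu, thresholds)
    if majority:
        labels = majority_filter(labels)
    return split_lumen_background(labels, seed=lumen_seed, connectivity=connectivity)


def layer_volumes(labels: LayerLabelVolume) -> dict[Layer, float]:
    """Per-layer volume in mm³ (voxel count × voxel volume)."""
    voxel_mm3 = float(np.prod(labels.voxel_size)) * 1e-9  # µm³ → mm³
    counts = np.bincount(labels.labels.ravel(), minlength=len(Layer))
    return {layer: float(counts[int(layer)]) * voxel_mm3 for layer in Layer}


def tissue_volume_mm3(labels: LayerLabelVolume) -> float:
    """Tissue volume = intima + media + adventitia, in mm³."""
    vols = layer_volumes(labels)
    return sum(vols[layer] for layer in TISSUE_LAYERS)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise InputError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    total = int(mask_a.sum()) + int(mask_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / total


def default_thresholds() -> LayerThresholds:
    """Uncalibrated default HU intervals shipped with the package.

    Derived from the default phantom layer means; real acquisitions need
    thresholds calibrated to their own stain concentration and scanner.
    """
    ref = resources.files("vesselct").joinpath("config/default_thresholds.json")
    with resources.as_file(ref) as path:
        return LayerThresholds.from_json(path)
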