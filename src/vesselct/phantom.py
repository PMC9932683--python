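"""Synthetic contrast-enhanced micro-CT vessel phantoms with known ground truth.

The phantom is a layered cylinder (lumen / intima / media / adventitia)
immersed in an ethanol bath, digitized on an isotropic micrometre grid with
the cylinder axis along the slice axis.  The heavy-element stain binds
preferentially to collagen, so each voxel's noiseless attenuation is

    HU = layer_mean_hu[layer] + hu_per_collagen * collagen_fraction

where the collagen fraction interpolates linearly in radius across the media
(inner to outer band) and is zero in the lumen and the bath.  Partial-volume
blur (Gaussian, in voxels) is applied before additive Gaussian detector
noise, then pixels are stored DICOM-style as

    stored = round((HU - rescale_intercept) / rescale_slope), clipped to uint16.

Paired synthetic histology mimics a picrosirius-red section under crossed
polarizers: within a tissue mask each pixel is birefringent ("white") with
probability equal to the local planted collagen fraction, split between the
two analyser angles.  Only the area fraction matters for the downstream
statistic, so no fibre texture is synthesized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .ct_io import CTVolume
from .errors import ConfigurationError
from .histo_quant import HistologyTriplet
from .segmentation import Layer, LayerLabelVolume, LayerThresholds

__all__ = [
    "DEFAULT_LAYER_MEAN_HU",
    "PhantomSpec",
    "PhantomTruth",
    "HistologySpec",
    "CohortSample",
    "generate_ct_phantom",
    "generate_histology_triplet",
    "generate_cohort",
    "annulus_fraction_map",
    "annulus_region_masks",
    "thresholds_from_spec",
]

#: Default layer mean HU.  Uncalibrated free parameters: ethanol well below
#: tissue, intima < media < adventitia, distinct enough for disjoint intervals.
DEFAULT_LAYER_MEAN_HU: dict[Layer, float] = {
    Layer.BACKGROUND: 500.0,  # 70% ethanol bath
    Layer.LUMEN: 500.0,       # lumen is ethanol-filled too
    Layer.INTIMA: 2000.0,
    Layer.MEDIA: 3500.0,
    Layer.ADVENTITIA: 6500.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and acquisition parameters of one synthetic vessel.

    Radii are micrometres and must be strictly increasing
    ``lumen < intima_outer < media_outer < adventitia_outer`` with the
    adventitia fitting inside the grid.  ``media_collagen_gradient`` gives the
    collagen fraction at the inner and outer media boundary; ``hu_per_collagen``
    is the linear stain-contrast coefficient (HU per unit collagen fraction).
    ``blur_sigma`` is in voxels (partial-volume surrogate), ``noise_sigma`` in HU.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 6.0
    lumen_radius: float = 120.0
    intima_outer_radius: float = 156.0
    media_outer_radius: float = 300.0
    adventitia_outer_radius: float = 360.0
    layer_mean_hu: Mapping[Layer, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_MEAN_HU)
    )
    media_collagen_gradient: tuple[float, float] = (0.2, 0.6)
    hu_per_collagen: float = 2500.0
    noise_sigma: float = 150.0
    blur_sigma: float = 0.8
    rescale_slope: float = 1.0
    rescale_intercept: float = -1000.0
    rng_seed: int = 0
    sample_id: str = "phantom"

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 1 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        radii = (
            ("lumen_radius", self.lumen_radius),
            ("intima_outer_radius", self.intima_outer_radius),
            ("media_outer_radius", self.media_outer_radius),
            ("adventitia_outer_radius", self.adventitia_outer_radius),
        )
        for (name_a, a), (name_b, b) in zip(radii, radii[1:]):
            if not a < b:
                raise ConfigurationError(
                    f"radii must be strictly increasing: {name_a}={a} >= {name_b}={b}"
                )
        if self.lumen_radius <= 0:
            raise ConfigurationError("lumen_radius must be positive")
        half_extent = min(self.grid_shape[1], self.grid_shape[2]) / 2.0 * self.voxel_size
        if self.adventitia_outer_radius >= half_extent:
            raise ConfigurationError(
                f"adventitia_outer_radius={self.adventitia_outer_radius} does not fit "
                f"inside the grid (half-extent {half_extent} um)"
            )
        for i, f in enumerate(self.media_collagen_gradient):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"media_collagen_gradient[{i}]={f} outside [0, 1]"
                )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if self.rescale_slope == 0:
            raise ConfigurationError("rescale_slope must be nonzero")
        missing = [l.name for l in Layer if l not in self.layer_mean_hu]
        if missing:
            raise ConfigurationError(f"layer_mean_hu missing layers: {missing}")

    # -- plain-config serialization -------------------------------------
    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "grid_shape", "voxel_size", "lumen_radius", "intima_outer_radius",
                "media_outer_radius", "adventitia_outer_radius",
                "media_collagen_gradient", "hu_per_collagen", "noise_sigma",
                "blur_sigma", "rescale_slope", "rescale_intercept", "rng_seed",
                "sample_id",
            )
        }
        d["grid_shape"] = list(self.grid_shape)
        d["media_collagen_gradient"] = list(self.media_collagen_gradient)
        d["layer_mean_hu"] = {Layer(k).name.lower(): v for k, v in self.layer_mean_hu.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhantomSpec":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["media_collagen_gradient"] = tuple(d["media_collagen_gradient"])
        d["layer_mean_hu"] = {
            Layer[k.upper()]: float(v) for k, v in d["layer_mean_hu"].items()
        }
        return cls(**d)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom: labels, planted collagen
    field, pre-noise HU, and exact per-layer volumes (mm³)."""

    label_volume: LayerLabelVolume
    collagen_field: np.ndarray
    noiseless_hu: np.ndarray
    layer_volumes_mm3: dict[Layer, float]

    @property
    def tissue_volume_mm3(self) -> float:
        return sum(
            self.layer_volumes_mm3[l] for l in (Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA)
        )


def _radius_map(spec: PhantomSpec) -> np.ndarray:
    """Radial distance (µm) of every in-plane pixel center from the cylinder axis."""
    _, n_rows, n_cols = spec.grid_shape
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    rr, cc_idx = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    return spec.voxel_size * np.hypot(rr - cr, cc_idx - cc)


def _label_slice(spec: PhantomSpec, radius: np.ndarray) -> np.ndarray:
    labels = np.full(radius.shape, int(Layer.BACKGROUND), dtype=np.uint8)
    labels[radius < spec.adventitia_outer_radius] = int(Layer.ADVENTITIA)
    labels[radius < spec.media_outer_radius] = int(Layer.MEDIA)
    labels[radius < spec.intima_outer_radius] = int(Layer.INTIMA)
    labels[radius < spec.lumen_radius] = int(Layer.LUMEN)
    return labels


def _collagen_slice(spec: PhantomSpec, radius: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Planted collagen fraction: linear in radius across the media, 0 elsewhere.

    The intima and adventitia carry no explicit collagen field; their own
    collagen contribution is absorbed into their layer mean HU.
    """
    f_in, f_out = spec.media_collagen_gradient
    band = spec.media_outer_radius - spec.intima_outer_radius
    t = np.clip((radius - spec.intima_outer_radius) / band, 0.0, 1.0)
    collagen = np.where(labels == int(Layer.MEDIA), f_in + (f_out - f_in) * t, 0.0)
    return collagen


def generate_ct_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a layered-cylinder CT phantom and its ground truth.

    Deterministic under ``spec.rng_seed``: identical specs give bit-identical
    stored-pixel arrays.
    """
    spec.validate()
    radius = _radius_map(spec)
    label_slice = _label_slice(spec, radius)
    collagen_slice = _collagen_slice(spec, radius, label_slice)

    mean_hu = np.zeros(len(Layer))
    for layer in Layer:
        mean_hu[int(layer)] = spec.layer_mean_hu[layer]
    hu_slice = mean_hu[label_slice] + spec.hu_per_collagen * collagen_slice

    n_slices = spec.grid_shape[0]
    labels = np.broadcast_to(label_slice, spec.grid_shape).copy()
    collagen = np.broadcast_to(collagen_slice, spec.grid_shape).copy()
    noiseless = np.broadcast_to(hu_slice, spec.grid_shape).astype(np.float64).copy()

    hu = noiseless
    if spec.blur_sigma > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=hu.shape)

    stored = np.rint((hu - spec.rescale_intercept) / spec.rescale_slope)
    stored = np.clip(stored, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    voxel = (spec.voxel_size,) * 3
    ct = CTVolume(
        stored_pixels=stored,
        rescale_slope=spec.rescale_slope,
        rescale_intercept=spec.rescale_intercept,
        voxel_size=voxel,
        sample_id=spec.sample_id,
    )
    label_volume = LayerLabelVolume(labels=labels, voxel_size=voxel)
    voxel_mm3 = spec.voxel_size**3 * 1e-9
    counts = np.bincount(labels.ravel(), minlength=len(Layer))
    truth = PhantomTruth(
        label_volume=label_volume,
        collagen_field=collagen,
        noiseless_hu=noiseless,
        layer_volumes_mm3={l: float(counts[int(l)]) * voxel_mm3 for l in Layer},
    )
    return ct, truth


def thresholds_from_spec(spec: PhantomSpec, margin: float = 1000.0) -> LayerThresholds:
    """HU intervals separating a phantom's layers, boundaries at midpoints.

    The media interval spans the full collagen-contrast range.  Because lumen
    and bath share the ethanol HU, the lumen interval also captures the
    background; :func:`vesselct.segmentation.split_lumen_background` separates
    them afterwards.
    """
    ethanol = spec.layer_mean_hu[Layer.LUMEN]
    intima = spec.layer_mean_hu[Layer.INTIMA]
    f_lo, f_hi = sorted(spec.media_collagen_gradient)
    media_lo = spec.layer_mean_hu[Layer.MEDIA] + spec.hu_per_collagen * f_lo
    media_hi = spec.layer_mean_hu[Layer.MEDIA] + spec.hu_per_collagen * f_hi
    adventitia = spec.layer_mean_hu[Layer.ADVENTITIA]
    b1 = (ethanol + intima) / 2.0
    b2 = (intima + media_lo) / 2.0
    b3 = (media_hi + adventitia) / 2.0
    return LayerThresholds(
        intervals={
            Layer.LUMEN: (ethanol - margin, b1),
            Layer.INTIMA: (b1, b2),
            Layer.MEDIA: (b2, b3),
            Layer.ADVENTITIA: (b3, adventitia + (adventitia - b3)),
        }
    )


# ---------------------------------------------------------------------------
# Synthetic histology
# ---------------------------------------------------------------------------

@dataclass
class HistologySpec:
    """Target collagen-fraction map and tissue mask for one synthetic section.

    ``collagen_fraction_map`` may be a scalar (uniform fraction inside the
    tissue) or a per-pixel array; it must be zero outside ``tissue_mask``.
    ``birefringence_split`` is the probability a birefringent pixel shows in
    the 0° rather than the 90° analyser image.
    """

    image_shape: tuple[int, int]
    collagen_fraction_map: np.ndarray | float
    tissue_mask: np.ndarray | None = None
    birefringence_split: float = 0.5
    speckle_seed: int = 0
    pixel_size: float = 1.0
    sample_id: str = ""
    section_id: str = ""

    def validate(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (fraction_map, tissue_mask) as full arrays after checks."""
        shape = tuple(int(n) for n in self.image_shape)
        if len(shape) != 2 or any(n < 1 for n in shape):
            raise ConfigurationError("image_shape must be two positive integers")
        mask = (
            np.ones(shape, dtype=bool)
            if self.tissue_mask is None
            else np.asarray(self.tissue_mask, dtype=bool)
        )
        if mask.shape != shape:
            raise ConfigurationError("tissue_mask shape must match image_shape")
        fmap = np.broadcast_to(np.asarray(self.collagen_fraction_map, dtype=np.float64), shape).copy()
        if fmap.min() < 0.0 or fmap.max() > 1.0:
            raise ConfigurationError("collagen_fraction_map values must lie in [0, 1]")
        fmap[~mask] = 0.0
        if not 0.0 <= self.birefringence_split <= 1.0:
            raise ConfigurationError("birefringence_split must lie in [0, 1]")
        return fmap, mask


def generate_histology_triplet(spec: HistologySpec) -> HistologyTriplet:
    """Generate a synthetic brightfield + dual-PLM triplet.

    Each tissue pixel is birefringent with probability equal to the local
    collagen fraction (seeded Bernoulli draw); each birefringent pixel is
    assigned to the 0° image with probability ``birefringence_split`` and to
    the 90° image otherwise, so the union of white PLM pixels realizes the
    planted fraction.  Images are 8-bit, white on dark.
    """
    fmap, mask = spec.validate()
    rng = np.random.default_rng(spec.speckle_seed)
    birefringent = (rng.random(fmap.shape) < fmap) & mask
    goes_to_0 = rng.random(fmap.shape) < spec.birefringence_split

    brightfield = np.where(mask, 255, 0).astype(np.uint8)
    plm_0 = np.where(birefringent & goes_to_0, 255, 0).astype(np.uint8)
    plm_90 = np.where(birefringent & ~goes_to_0, 255, 0).astype(np.uint8)
    return HistologyTriplet(
        brightfield=brightfield,
        plm_0=plm_0,
        plm_90=plm_90,
        pixel_size=spec.pixel_size,
        sample_id=spec.sample_id,
        section_id=spec.section_id,
    )


def annulus_fraction_map(
    shape: tuple[int, int],
    inner_radius: float,
    outer_radius: float,
    fraction_inner: float,
    fraction_outer: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-shaped tissue mask with a radially interpolated collagen fraction.

    Mimics a media cross-section: the fraction runs linearly from
    ``fraction_inner`` at the inner edge to ``fraction_outer`` at the outer
    edge.  Returns ``(fraction_map, tissue_mask)`` in pixel units.
    """
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    rr, cc_idx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    radius = np.hypot(rr - cr, cc_idx - cc)
    mask = (radius >= inner_radius) & (radius < outer_radius)
    t = np.clip((radius - inner_radius) / (outer_radius - inner_radius), 0.0, 1.0)
    fmap = np.where(mask, fraction_inner + (fraction_outer - fraction_inner) * t, 0.0)
    return fmap, mask


def annulus_region_masks(
    shape: tuple[int, int], inner_radius: float, outer_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """(inner-third, outer-third) ring masks of an annulus — the histology
    analogues of the internal/external media ROIs."""
    third = (outer_radius - inner_radius) / 3.0
    _, inner = annulus_fraction_map(shape, inner_radius, inner_radius + third, 0, 0)
    _, outer = annulus_fraction_map(shape, outer_radius - third, outer_radius, 0, 0)
    return inner, outer


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSample:
    """One synthetic study sample: CT volume, ground truth and paired histology."""

    sample_id: str
    ct: CTVolume
    truth: PhantomTruth
    histology: HistologyTriplet
    spec: PhantomSpec
    volume_multiplier: float
    collagen_level: float


def _scaled_spec(
    base: PhantomSpec, multiplier: float, collagen_level: float, seed: int, sample_id: str,
    dilution: float = 1.0,
) -> PhantomSpec:
    s = multiplier ** (1.0 / 3.0)
    f_in, f_out = base.media_collagen_gradient
    half = abs(f_out - f_in) / 2.0
    gradient = (
        float(np.clip(collagen_level - half, 0.0, 1.0)),
        float(np.clip(collagen_level + half, 0.0, 1.0)),
    )
    mean_hu = dict(base.layer_mean_hu)
    if dilution != 1.0:
        # Larger samples dilute the stain: tissue attenuation scales down,
        # the ethanol bath/lumen is unaffected.
        for layer in (Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA):
            mean_hu[layer] = mean_hu[layer] / dilution
    return replace(
        base,
        grid_shape=tuple(max(1, round(n * s)) for n in base.grid_shape),
        lumen_radius=base.lumen_radius * s,
        intima_outer_radius=base.intima_outer_radius * s,
        media_outer_radius=base.media_outer_radius * s,
        adventitia_outer_radius=base.adventitia_outer_radius * s,
        media_collagen_gradient=gradient,
        layer_mean_hu=mean_hu,
        hu_per_collagen=base.hu_per_collagen / dilution,
        rng_seed=seed,
        sample_id=sample_id,
    )


def generate_cohort(
    n_samples: int,
    base_spec: PhantomSpec | None = None,
    volume_multipliers: Sequence[float] | None = None,
    collagen_levels: Sequence[float] | None = None,
    seed: int = 0,
    dilute_stain_by_volume: bool = False,
    histology_shape: tuple[int, int] = (192, 192),
) -> list[CohortSample]:
    """Generate a cohort of phantoms with paired synthetic histology.

    Sample *i* scales every radius and the grid extent by the cube root of
    ``volume_multipliers[i]`` (so tissue volume scales by the multiplier) and
    centers the media collagen gradient on ``collagen_levels[i]``; its
    histology is an annular section carrying the same radial collagen
    gradient.  With ``dilute_stain_by_volume`` the tissue HU (layer means and
    collagen contrast) is divided by the sample's volume ratio to the smallest
    sample, emulating stain dilution in larger samples — the confound the
    volume normalization of the downstream statistics is designed to remove.
    Deterministic under ``seed``.
    """
    if base_spec is None:
        base_spec = PhantomSpec()
    if volume_multipliers is None:
        # modest spread, as for same-length segments cut from a few vessels
        volume_multipliers = list(np.linspace(1.0, 2.0, n_samples))
    if collagen_levels is None:
        collagen_levels = list(np.linspace(0.25, 0.75, n_samples))
    if len(volume_multipliers) != n_samples or len(collagen_levels) != n_samples:
        raise ConfigurationError(
            f"volume_multipliers and collagen_levels must have length {n_samples}"
        )
    if any(m <= 0 for m in volume_multipliers):
        raise ConfigurationError("volume multipliers must be positive")

    min_multiplier = min(volume_multipliers)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2 * n_samples)
    ]
    samples: list[CohortSample] = []
    for i in range(n_samples):
        sample_id = f"sample_{i:02d}"
        dilution = volume_multipliers[i] / min_multiplier if dilute_stain_by_volume else 1.0
        spec = _scaled_spec(
            base_spec, volume_multipliers[i], collagen_levels[i],
            seed=child_seeds[2 * i], sample_id=sample_id, dilution=dilution,
        )
        ct, truth = generate_ct_phantom(spec)
        outer = 0.45 * min(histology_shape)
        fmap, mask = annulus_fraction_map(
            histology_shape, 0.5 * outer, outer, *spec.media_collagen_gradient
        )
        histology = generate_histology_triplet(
            HistologySpec(
                image_shape=histology_shape,
                collagen_fraction_map=fmap,
                tissue_mask=mask,
                speckle_seed=child_seeds[2 * i + 1],
                sample_id=sample_id,
                section_id="section_00",
            )
        )
        samples.append(
            CohortSample(
                sample_id=sample_id,
                ct=ct,
                truth=truth,
                histology=histology,
                spec=spec,
                volume_multiplier=float(volume_multipliers[i]),
                collagen_level=float(collagen_levels[i]),
            )
        )
    return samples
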