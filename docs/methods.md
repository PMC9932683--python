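# Methods

## The measurement problem

Collagen is the main load-bearing constituent of the arterial wall, and its
content and arrangement relate to the mechanical integrity of vessels and
atherosclerotic plaques. Histology with picrosirius red (PSR) under
polarized light is the reference method but is destructive and 2D. A
heavy-element contrast stain that binds preferentially to collagen makes
collagen-rich tissue more attenuating in micro-CT, so Hounsfield Units (HU)
become a non-destructive, 3D proxy for collagen content — provided the
stain-to-tissue ratio is comparable across samples. `vesselct` implements
the quantification chain and the statistics that test the HU–collagen
relationship, with a synthetic-data module supplying ground-truth inputs.

## Phantom model

A vessel is modelled as a layered cylinder along the slice axis on an
isotropic grid (default 6 µm voxels, matching high-resolution ex-vivo
micro-CT of small arteries). Each in-plane pixel is classified by the
radial distance of its center: lumen, intima, media, adventitia, then bath.
Noiseless attenuation is

```
HU(v) = layer_mean_hu[layer(v)] + hu_per_collagen · c(v)
```

where the collagen fraction `c` interpolates linearly in radius across the
media from the internal to the external boundary value (default 0.2 → 0.6,
reflecting the collagen-richer external media) and is zero in the lumen and
bath. The intima and adventitia carry no explicit collagen field; their own
collagen contribution is absorbed into their layer means. A Gaussian blur in
voxel units (default σ = 0.8) stands in for partial-volume averaging and is
applied **before** additive Gaussian detector noise (default σ = 150 HU),
because partial volume is an acquisition effect upstream of the detector.
Stored pixels are `round((HU − intercept)/slope)` clipped to unsigned
16-bit, the DICOM convention.

Default layer means (HU): bath/lumen 500 ("ethanol"), intima 2000, media
3500 plus 2500 HU per unit collagen fraction (so 4000–5000 across the
default gradient), adventitia 6500. These are **uncalibrated free
parameters** chosen once to give distinct, well-ordered layers with the
bath far below tissue; absolute per-layer HU ranges of real stained
arteries depend on stain concentration and scanner settings and must be
calibrated per protocol. The shipped
`config/default_thresholds.json` is derived from these means (interval
boundaries at midpoints between adjacent layer levels) and is marked
uncalibrated for the same reason.

### Synthetic histology

Only the *area fraction* of birefringent pixels enters the collagen
statistic, so no fibre texture is synthesized: within a tissue mask, each
pixel is white with probability equal to the local planted collagen
fraction (seeded Bernoulli draw), and each white pixel is assigned to the
0° or 90° analyser image by a second draw (`birefringence_split`, default
0.5). The union of the two PLM images therefore realizes the planted
fraction up to binomial error (~0.002 at 256²). Cohort sections are
annuli with the same radial collagen gradient as the CT media.

### Cohorts and the dilution confound

`generate_cohort` scales each sample's radii **and** grid extent by the
cube root of its volume multiplier, so voxel-counted tissue volume scales
by the multiplier itself. Default multipliers span 1–2 (same-length
segments cut from a few vessels differ modestly in volume); the media
collagen gradient is re-centered on each sample's collagen level with the
base half-span. With `dilute_stain_by_volume`, tissue-layer means and the
collagen contrast are divided by the sample's volume ratio to the smallest
sample — a multiplicative dilution that the downstream volume
normalization (multiply mean HU by the volume ratio) exactly undoes. This
is the simplest confound structure consistent with a fixed stain bath
spread over more tissue, and it is deliberately matched to the form of the
correction under study.

## Segmentation

HU intervals are half-open `[low, high)`; a value on a shared boundary
belongs to the interval starting there. Overlapping intervals resolve by a
fixed priority (adventitia > media > intima > lumen — the denser stain
wins). Voxels in no interval are background. Lumen and bath share the
ethanol interval, so after classification the lumen label is kept only on
the connected component (default 6-connectivity) containing a lumen seed —
the automated equivalent of a viewer's grow-region click. If the seed
voxel itself was flipped by noise, it snaps to the nearest candidate within
5 voxels (configurable; 0 disables snapping). An optional 3×3×3 majority
filter (off by default in the segmentation API, enabled by the pipeline's
segmentation path) removes speckle from noisy classifications; ties go to
the lowest label value.

`grow_region` itself is general seeded region growing: the connected
component of the in-interval voxel set containing the seed, under 6- or
26-connectivity (default 6 — conservative growth leaks less through noise
bridges). Tests verify it against an exhaustive breadth-first flood fill.

Per-sample thresholds for phantoms are derived from the sample's own layer
means (`thresholds_from_spec`), mirroring the protocol caveat that fixed
thresholds are only valid at constant stain concentration and scan
settings.

## ROI protocol and profiles

Disc membership is pixel-center distance strictly less than the radius —
fixed once for reproducibility. The default protocol is 3 internal + 3
external ROIs on each of 3 slices (counts configurable); the per-region
grand mean is the unweighted mean of the ROI means. "Internal" and
"external" media are the inner and outer radial thirds of the media band —
the boundary is not anatomically defined, and a third-based split is
symmetric and auditable. Automatic placement estimates the band per slice
from the media labels after a binary opening and largest-component cleanup
(noise speckle and partial-volume rings at other interfaces can alias into
the media interval), targets the mid-radius of each third, spreads ROIs in
angle with a seeded offset, and requires every disc to lie entirely on
media labels, nudging in angle and radius before failing with advice to
reduce the radius.

Line profiles use bilinear interpolation at equally spaced points
(profiles are continuous curves, not voxel staircases), with positions in
µm from the voxel spacing. The window/level display transform maps
`[level − width/2, level + width/2]` to 0–255, rounding half-up so the
midpoint is exactly 128; it is display-only and never feeds quantification.

## Histology quantification

The two PLM images combine by pixelwise maximum: a fibre extinguished at
one analyser angle is bright at the other, and maximum keeps the brighter
signal without the overflow that addition would cause. Binarization is
Otsu by default (parameter-free and reproducible) with a fixed threshold
available; a constant image under Otsu raises an error advising the fixed
method, except that an all-zero combined PLM image is treated as zero
collagen (a section genuinely without birefringent signal). The numerator
of the collagen statistic is intersected with the brightfield tissue mask,
guaranteeing content in [0, 1]. Brightfield images with dark tissue on a
bright background are inverted on load via a manifest flag, since the
pixel-count formula presumes tissue = white.

## Statistics

`volume_normalize` computes `ratio_i = V_i / min_j V_j` and
`normalized_hu_i = mean_hu_i × ratio_i`. Multiplying an attenuation value
by a relative volume has no direct physical interpretation; it is
implemented exactly as stated because it is the correction whose effect the
package measures. Pearson's r (scipy) with the two-sided t-transform
p-value (n−2 df) is the only inferential statistic; a single planned test,
so no multiple-testing correction. Cohort analysis defaults to pooling
region-level observations (internal and external media per sample, giving
2n points) with a `level="sample"` switch that averages regions first —
both are provided because either pooling is defensible and they answer
slightly different questions.

## Problem sizes and numerical choices

Tests and the acceptance script run phantoms between 16×72×72 and 128³
voxels and cohorts of six samples, sizes at which every geometric quantity
is still resolved (media band ≥ 12 voxels at the smallest scale) while
whole-suite runtimes stay in seconds to minutes. Determinism: every random
draw flows from an explicit seed through `numpy.random.default_rng` /
`SeedSequence.spawn`; identical seeds give bit-identical stored-pixel
arrays. Boundary conventions (half-open intervals, strict disc membership,
round-half-up windowing, ties-to-lowest-label majority filter) are each
fixed explicitly because the quantities they affect are otherwise
ill-defined at measure-zero boundaries.

## What passing tests do and do not show

The phantoms validate the *pipeline*: that conversion, segmentation, ROI
averaging, the collagen statistic and the normalization recover planted
ground truth under noise, blur and a volume-proportional dilution
confound. They do not emulate fibre texture or orientation, beam
hardening or other X-ray physics, staining-diffusion kinetics, histology
processing artifacts (wrinkling, tearing, compression), or imperfect
CT–histology pairing. In particular, the near-perfect normalized
correlations on synthetic cohorts arise because the planted dilution is
exactly multiplicative in volume; real cohorts, where dilution is only
approximately so and biological variability enters, should expect
moderate correlations. Headline correlation values from any specific real
dataset are therefore not reproducible from this package alone; what the
package establishes is the qualitative structure — volume normalization
reveals an HU–collagen association that raw HU masks, and the external
media reads higher HU than the internal media when its collagen fraction
is higher.
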