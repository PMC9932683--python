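# vesselct

Quantification of arterial collagen from contrast-enhanced micro-CT with
histological validation.

Heavy-element stains such as phosphotungstic acid (PTA) bind preferentially
to collagen, so a stained artery imaged by micro-CT carries collagen
information in its Hounsfield Units (HU). `vesselct` implements the full
quantification workflow around that idea:

* **HU conversion** — DICOM series in, `HU = stored_pixels × slope + intercept`
  from the rescale header.
* **Layer segmentation** — half-open per-layer HU intervals classify voxels
  into lumen / intima / media / adventitia; seeded region growing separates
  the ethanol-filled lumen from the ethanol bath; Dice overlap validates
  against ground truth.
* **Media ROI panel** — three circular ROIs in the internal media and three
  in the external media (inner/outer radial thirds of the media band) on each
  of three slices, averaged per region.
* **Histological collagen content** — a picrosirius-red section imaged in
  brightfield plus two polarized-light (PLM) images 90° apart; the PLM pair
  is combined by pixelwise maximum, both images are binarized, and

  `collagen content = (white PLM pixels in ROI ∩ tissue) / (white brightfield pixels in ROI)`

* **Volume-normalized correlation** — a fixed stain bath dilutes over larger
  samples, masking the HU–collagen association across a cohort. Each
  sample's tissue volume is divided by the cohort's smallest volume to give
  a normalizing ratio (exactly 1 for the smallest sample), mean HU is
  multiplied by that ratio, and Pearson's *r* between (normalized) HU and
  histological collagen content is reported.

Because no raw arterial scans ship with the package, a first-class
**phantom module** generates layered cylindrical vessels with a planted
radial collagen gradient in the media, DICOM-style stored-pixel encoding,
partial-volume blur and detector noise, plus paired synthetic PLM histology
— every stage is testable end to end with known ground truth.

## Worked example

`examples/05_cohort_correlation.py` generates a six-sample cohort whose
stain intensity is diluted in proportion to tissue volume, segments each
volume, measures the media ROI panels and histology, and correlates:

```
raw HU vs collagen:        r = -0.414 (p = 0.181)
volume-normalized HU:      r = +0.991 (p = 4.84e-10)
mean external-internal media HU contrast: +511 HU
```

The raw correlation is negative because larger (more diluted) samples read
lower HU regardless of collagen; multiplying by the volume ratio undoes the
dilution and the positive HU–collagen association emerges. The +511 HU
internal→external contrast reflects the planted outward collagen gradient in
the media. The other scripts in `examples/` walk through phantom generation
and DICOM export, segmentation with Dice validation, ROI panels with line
profiles and window/level display, and histology quantification.

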