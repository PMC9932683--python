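"""End-to-end cohort analysis: stain dilution masks the HU-collagen
association and volume normalization recovers it.

Six phantoms of varying tissue volume and media collagen level are generated
with stain intensity diluted in larger samples.  Each is segmented, its
media ROI panel measured, and its paired histology quantified.  Pearson's r
is computed between mean HU and collagen content before and after
multiplying HU by the sample's tissue-volume ratio to the smallest sample.
"""

from vesselct import PhantomSpec, analyze_synthetic_cohort

base = PhantomSpec(
    grid_shape=(16, 128, 128),
    lumen_radius=85.0, intima_outer_radius=110.0,
    media_outer_radius=210.0, adventitia_outer_radius=250.0,
)
result = analyze_synthetic_cohort(
    n_samples=6, base_spec=base, seed=1,
    dilute_stain_by_volume=True, label_source="segmentation",
)

cols = ["sample_id", "region_tag", "tissue_volume_mm3", "mean_hu",
        "normalizing_ratio", "normalized_hu", "collagen_content"]
print(result.records[cols].round(3).to_string(index=False))
print()
print(f"raw HU vs collagen:        r = {result.raw.r:+.3f} (p = {result.raw.p_value:.3f})")
print(f"volume-normalized HU:      r = {result.normalized.r:+.3f} "
      f"(p = {result.normalized.p_value:.2e})")
print(f"mean external-internal media HU contrast: "
      f"{result.region_contrast['external_minus_internal'].mean():+.0f} HU")
# Raw r is near zero or negative because larger samples are stain-diluted;
# normalization undoes the dilution and the positive HU-collagen association
# emerges.
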