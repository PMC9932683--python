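"""Phantom generator: closed-form HU model, determinism, cohort scaling."""

from dataclasses import replace

import numpy as np
import pytest

from vesselct import (
    HistologySpec,
    Layer,
    PhantomSpec,
    generate_cohort,
    generate_ct_phantom,
    generate_histology_triplet,
)
from vesselct.errors import ConfigurationError

from conftest import small_spec


def closed_form_hu(spec: PhantomSpec) -> np.ndarray:
    """Independent per-voxel recomputation of the noiseless layered-cylinder HU."""
    nz, nr, nc = spec.grid_shape
    cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    out = np.empty(spec.grid_shape)
    f_in, f_out = spec.media_collagen_gradient
    for r in range(nr):
        for c in range(nc):
            rad = spec.voxel_size * np.hypot(r - cr, c - cc)
            if rad < spec.lumen_radius:
                hu = spec.layer_mean_hu[Layer.LUMEN]
            elif rad < spec.intima_outer_radius:
                hu = spec.layer_mean_hu[Layer.INTIMA]
            elif rad < spec.media_outer_radius:
                t = (rad - spec.intima_outer_radius) / (
                    spec.media_outer_radius - spec.intima_outer_radius
                )
                hu = spec.layer_mean_hu[Layer.MEDIA] + spec.hu_per_collagen * (
                    f_in + (f_out - f_in) * t
                )
            elif rad < spec.adventitia_outer_radius:
                hu = spec.layer_mean_hu[Layer.ADVENTITIA]
            else:
                hu = spec.layer_mean_hu[Layer.BACKGROUND]
            out[:, r, c] = hu
    return out


def test_noiseless_hu_matches_closed_form_model():
    spec = small_spec(grid_shape=(3, 48, 48), lumen_radius=40, intima_outer_radius=52,
                      media_outer_radius=100, adventitia_outer_radius=120,
                      noise_sigma=0.0, blur_sigma=0.0)
    _, truth = generate_ct_phantom(spec)
    np.testing.assert_allclose(truth.noiseless_hu, closed_form_hu(spec), rtol=0, atol=1e-9)


def test_constant_layer_hu_without_contrast():
    spec = small_spec(noise_sigma=0.0, blur_sigma=0.0, hu_per_collagen=0.0,
                      layer_mean_hu={**dict(PhantomSpec().layer_mean_hu), Layer.MEDIA: 4000.0})
    ct, truth = generate_ct_phantom(spec)
    media = truth.label_volume.mask(Layer.MEDIA)
    hu = ct.stored_pixels.astype(float) * spec.rescale_slope + spec.rescale_intercept
    assert np.all(hu[media] == 4000.0)


def test_media_gradient_contrast_across_band():
    """HU rise across the media equals hu_per_collagen times the fraction gap."""
    spec = small_spec(noise_sigma=0.0, blur_sigma=0.0, hu_per_collagen=5000.0,
                      media_collagen_gradient=(0.2, 0.6))
    _, truth = generate_ct_phantom(spec)
    media = truth.label_volume.mask(Layer.MEDIA)[0]
    nr = spec.grid_shape[1]
    cr = (nr - 1) / 2.0
    rad = spec.voxel_size * np.hypot(
        *np.meshgrid(np.arange(nr) - cr, np.arange(spec.grid_shape[2]) - cr, indexing="ij")
    )
    hu0 = truth.noiseless_hu[0]
    inner = hu0[media & (rad < spec.intima_outer_radius + spec.voxel_size)]
    outer = hu0[media & (rad > spec.media_outer_radius - spec.voxel_size)]
    band_voxels = (spec.media_outer_radius - spec.intima_outer_radius) / spec.voxel_size
    tol = 2000.0 / band_voxels  # one voxel of linear interpolation
    assert abs((outer.max() - inner.min()) - 2000.0) <= 2 * tol


def test_invalid_radii_name_the_field():
    with pytest.raises(ConfigurationError, match="lumen_radius"):
        generate_ct_phantom(small_spec(lumen_radius=80.0, intima_outer_radius=78.0))


@pytest.mark.parametrize(
    "overrides",
    [
        {"noise_sigma": -1.0},
        {"media_collagen_gradient": (0.2, 1.3)},
        {"adventitia_outer_radius": 5000.0},
        {"voxel_size": 0.0},
    ],
)
def test_invariant_violations_raise(overrides):
    with pytest.raises(ConfigurationError):
        generate_ct_phantom(small_spec(**overrides))


def test_seeded_determinism():
    spec = small_spec(rng_seed=42)
    ct1, _ = generate_ct_phantom(spec)
    ct2, _ = generate_ct_phantom(spec)
    assert np.array_equal(ct1.stored_pixels, ct2.stored_pixels)
    ct3, _ = generate_ct_phantom(replace(spec, rng_seed=43))
    assert not np.array_equal(ct1.stored_pixels, ct3.stored_pixels)


def test_more_stain_contrast_raises_media_mean():
    lo, _ = generate_ct_phantom(small_spec(hu_per_collagen=1000.0, noise_sigma=0, blur_sigma=0))
    hi, truth = generate_ct_phantom(small_spec(hu_per_collagen=3000.0, noise_sigma=0, blur_sigma=0))
    media = truth.label_volume.mask(Layer.MEDIA)
    assert hi.stored_pixels[media].mean() > lo.stored_pixels[media].mean()


def test_spec_json_round_trip(tmp_path):
    spec = small_spec(rng_seed=7, hu_per_collagen=1234.5)
    path = tmp_path / "spec.json"
    spec.save_json(path)
    assert PhantomSpec.load_json(path) == spec


# ---------------------------------------------------------------------------
# Synthetic histology
# ---------------------------------------------------------------------------

def test_saturated_fraction_fills_tissue_exactly():
    mask = np.zeros((64, 64), dtype=bool)
    mask[8:56, 8:56] = True
    triplet = generate_histology_triplet(
        HistologySpec(image_shape=(64, 64), collagen_fraction_map=1.0, tissue_mask=mask)
    )
    combined = np.maximum(triplet.plm_0, triplet.plm_90) > 0
    assert np.array_equal(combined, mask)
    assert np.array_equal(triplet.brightfield > 0, mask)


def test_zero_fraction_gives_dark_plm_images():
    triplet = generate_histology_triplet(
        HistologySpec(image_shape=(32, 32), collagen_fraction_map=0.0)
    )
    assert triplet.plm_0.max() == 0 and triplet.plm_90.max() == 0


def test_half_fraction_realized_within_binomial_error():
    triplet = generate_histology_triplet(
        HistologySpec(image_shape=(256, 256), collagen_fraction_map=0.5, speckle_seed=11)
    )
    white = (np.maximum(triplet.plm_0, triplet.plm_90) > 0).mean()
    assert abs(white - 0.5) < 0.02  # binomial SE ~ 0.002 at n = 65536


def test_plm_images_partition_the_birefringent_set():
    triplet = generate_histology_triplet(
        HistologySpec(image_shape=(128, 128), collagen_fraction_map=0.4, speckle_seed=3)
    )
    both = (triplet.plm_0 > 0) & (triplet.plm_90 > 0)
    assert not both.any()


def test_fraction_outside_unit_interval_rejected():
    with pytest.raises(ConfigurationError):
        generate_histology_triplet(
            HistologySpec(image_shape=(16, 16), collagen_fraction_map=1.5)
        )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def test_unit_multiplier_preserves_tissue_volume():
    base = small_spec()
    (sample,) = generate_cohort(
        1, base_spec=base, volume_multipliers=[1.0],
        collagen_levels=[0.4], seed=0,
    )
    _, truth = generate_ct_phantom(replace(base, media_collagen_gradient=sample.spec.media_collagen_gradient))
    assert sample.truth.tissue_volume_mm3 == pytest.approx(truth.tissue_volume_mm3)


def test_volume_scales_with_multiplier():
    """Cube-root radius/extent scaling makes voxel-counted volume track the multiplier."""
    base = small_spec(grid_shape=(16, 160, 160))
    samples = generate_cohort(
        2, base_spec=base, volume_multipliers=[1.0, 8.0],
        collagen_levels=[0.4, 0.4], seed=0,
    )
    ratio = samples[1].truth.tissue_volume_mm3 / samples[0].truth.tissue_volume_mm3
    assert ratio == pytest.approx(8.0, rel=0.02)


def test_cohort_is_deterministic_under_seed():
    base = small_spec()
    a = generate_cohort(3, base_spec=base, volume_multipliers=[1, 1.2, 1.5],
                        collagen_levels=[0.3, 0.5, 0.7], seed=9)
    b = generate_cohort(3, base_spec=base, volume_multipliers=[1, 1.2, 1.5],
                        collagen_levels=[0.3, 0.5, 0.7], seed=9)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.ct.stored_pixels, sb.ct.stored_pixels)
        assert np.array_equal(sa.histology.plm_0, sb.histology.plm_0)


def test_cohort_length_mismatch_rejected():
    with pytest.raises(ConfigurationError):
        generate_cohort(3, base_spec=small_spec(), volume_multipliers=[1.0],
                        collagen_levels=[0.3, 0.5, 0.7], seed=0)


def test_stain_dilution_lowers_large_sample_hu():
    base = small_spec(noise_sigma=0.0, blur_sigma=0.0)
    plain = generate_cohort(2, base_spec=base, volume_multipliers=[1.0, 2.0],
                            collagen_levels=[0.5, 0.5], seed=0)
    diluted = generate_cohort(2, base_spec=base, volume_multipliers=[1.0, 2.0],
                              collagen_levels=[0.5, 0.5], seed=0,
                              dilute_stain_by_volume=True)
    media_plain = plain[1].truth.label_volume.mask(Layer.MEDIA)
    media_dil = diluted[1].truth.label_volume.mask(Layer.MEDIA)
    assert (
        diluted[1].ct.stored_pixels[media_dil].mean()
        < plain[1].ct.stored_pixels[media_plain].mean() / 1.5
    )
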