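"""Threshold classification, region growing (vs BFS oracle), volumes, Dice."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from vesselct import (
    HUVolume,
    Layer,
    LayerLabelVolume,
    LayerThresholds,
    SeedPoint,
    classify_by_threshold,
    default_thresholds,
    dice,
    generate_ct_phantom,
    grow_region,
    layer_volumes,
    majority_filter,
    segment_vessel,
    thresholds_from_spec,
    tissue_volume_mm3,
    to_hounsfield,
)
from vesselct.errors import ConfigurationError, InputError, SeedError

from conftest import small_spec


def bfs_flood_fill(mask: np.ndarray, seed: tuple, connectivity: int) -> np.ndarray:
    """Exhaustive breadth-first flood fill; the independent region-grow oracle."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    out = np.zeros_like(mask, dtype=bool)
    if not mask[seed]:
        return out
    out[seed] = True
    queue = deque([seed])
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= ni < s for ni, s in zip(n, mask.shape)) and mask[n] and not out[n]:
                out[n] = True
                queue.append(n)
    return out


# ---------------------------------------------------------------------------
# Threshold classification
# ---------------------------------------------------------------------------

def test_noiseless_phantom_recovers_truth_at_tissue_voxels(clean_phantom, clean_thresholds):
    spec, _, truth, hu = clean_phantom
    labels = classify_by_threshold(hu, clean_thresholds)
    tissue = np.isin(truth.label_volume.labels, [int(l) for l in
                                                 (Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA)])
    assert np.array_equal(labels.labels[tissue], truth.label_volume.labels[tissue])
    # oracle: brute-force interval membership on a random voxel subset
    rng = np.random.default_rng(0)
    idx = tuple(rng.integers(0, s, 200) for s in hu.shape)
    for z, y, x in zip(*idx):
        value = hu.hu[z, y, x]
        expected = Layer.BACKGROUND
        for layer in (Layer.LUMEN, Layer.INTIMA, Layer.MEDIA, Layer.ADVENTITIA):
            low, high = clean_thresholds.intervals[layer]
            if low <= value < high:
                expected = layer
        assert labels.labels[z, y, x] == int(expected)


def test_intervals_missing_volume_range_give_background(clean_phantom):
    _, _, _, hu = clean_phantom
    far = LayerThresholds(intervals={Layer.MEDIA: (1e6, 2e6)})
    labels = classify_by_threshold(hu, far)
    assert (labels.labels == int(Layer.BACKGROUND)).all()


def test_shared_boundary_goes_to_higher_interval():
    hu = HUVolume(hu=np.full((1, 1, 1), 3000.0))
    thresholds = LayerThresholds(
        intervals={Layer.INTIMA: (1000.0, 3000.0), Layer.MEDIA: (3000.0, 5000.0)}
    )
    labels = classify_by_threshold(hu, thresholds)
    assert labels.labels[0, 0, 0] == int(Layer.MEDIA)


def test_invalid_interval_rejected():
    with pytest.raises(ConfigurationError):
        LayerThresholds(intervals={Layer.MEDIA: (5000.0, 3000.0)})


def test_labels_partition_volume(clean_phantom, clean_thresholds):
    _, _, _, hu = clean_phantom
    labels = classify_by_threshold(hu, clean_thresholds)
    assert labels.labels.shape == hu.shape  # every voxel has exactly one label value


def test_classification_invariant_to_common_affine_shift(clean_phantom, clean_thresholds):
    _, _, _, hu = clean_phantom
    shifted = HUVolume(hu=hu.hu + 750.0, voxel_size=hu.voxel_size)
    shifted_thresholds = LayerThresholds(
        intervals={l: (lo + 750.0, hi + 750.0) for l, (lo, hi) in clean_thresholds.intervals.items()}
    )
    a = classify_by_threshold(hu, clean_thresholds)
    b = classify_by_threshold(shifted, shifted_thresholds)
    assert np.array_equal(a.labels, b.labels)


def test_default_thresholds_load_and_segment(clean_phantom):
    _, _, truth, hu = clean_phantom
    labels = segment_vessel(hu, default_thresholds())
    assert dice(labels.mask(Layer.MEDIA), truth.label_volume.mask(Layer.MEDIA)) == 1.0


def test_thresholds_json_round_trip(tmp_path, clean_thresholds):
    path = tmp_path / "thresholds.json"
    clean_thresholds.to_json(path)
    assert LayerThresholds.from_json(path).intervals == clean_thresholds.intervals


# ---------------------------------------------------------------------------
# Region growing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("connectivity", [6, 26])
def test_grow_region_matches_bfs_oracle(connectivity):
    rng = np.random.default_rng(1)
    for _ in range(5):
        hu = HUVolume(hu=rng.uniform(0, 100, size=(16, 16, 16)))
        interval = (40.0, 60.0)
        mask = (hu.hu >= interval[0]) & (hu.hu < interval[1])
        seeds = np.argwhere(mask)
        seed = tuple(seeds[rng.integers(len(seeds))])
        grown = grow_region(hu, SeedPoint(seed), interval, connectivity=connectivity)
        assert np.array_equal(grown, bfs_flood_fill(mask, seed, connectivity))
        # always a connected subset of the thresholded mask
        assert np.all(mask[grown])


def test_grow_region_isolated_seed():
    hu_arr = np.zeros((3, 3, 3))
    hu_arr[1, 1, 1] = 50.0
    grown = grow_region(HUVolume(hu=hu_arr), SeedPoint((1, 1, 1)), (40.0, 60.0))
    assert grown.sum() == 1 and grown[1, 1, 1]


def test_grow_region_excludes_disconnected_blob():
    hu_arr = np.zeros((3, 5, 5))
    hu_arr[1, 1, 1] = 50.0  # blob A
    hu_arr[1, 3, 3] = 50.0  # blob B, disconnected under 6-connectivity
    grown = grow_region(HUVolume(hu=hu_arr), SeedPoint((1, 1, 1)), (40.0, 60.0), connectivity=6)
    assert grown[1, 1, 1] and not grown[1, 3, 3]


def test_grow_region_recovers_lumen_cylinder(clean_phantom):
    spec, _, truth, hu = clean_phantom
    ethanol = spec.layer_mean_hu[Layer.LUMEN]
    seed = SeedPoint((spec.grid_shape[0] // 2, spec.grid_shape[1] // 2, spec.grid_shape[2] // 2))
    grown = grow_region(hu, seed, (ethanol - 1.0, ethanol + 1.0))
    assert np.array_equal(grown, truth.label_volume.mask(Layer.LUMEN))


def test_seed_outside_interval_rejected(clean_phantom):
    _, _, _, hu = clean_phantom
    with pytest.raises(SeedError):
        grow_region(hu, SeedPoint((0, 0, 0)), (1e5, 2e5))


# ---------------------------------------------------------------------------
# Volumes and Dice
# ---------------------------------------------------------------------------

def test_layer_volume_unit_arithmetic():
    labels = np.zeros((1, 10, 1), dtype=np.uint8)
    labels[0, :, 0] = int(Layer.MEDIA)
    vols = layer_volumes(LayerLabelVolume(labels=labels, voxel_size=(6.0, 6.0, 6.0)))
    assert vols[Layer.MEDIA] == pytest.approx(10 * 216e-9)
    assert vols[Layer.INTIMA] == 0.0


def test_segmented_volumes_equal_truth_on_noiseless_phantom(clean_phantom, clean_thresholds):
    _, _, truth, hu = clean_phantom
    labels = segment_vessel(hu, clean_thresholds)
    seg_vols = layer_volumes(labels)
    for layer in Layer:
        assert seg_vols[layer] == pytest.approx(truth.layer_volumes_mm3[layer])
    assert tissue_volume_mm3(labels) == pytest.approx(truth.tissue_volume_mm3)


def test_dice_identities():
    a = np.zeros((2, 2, 2), dtype=bool)
    a[0] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
    assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0
    b = a.copy()
    b[1] = True  # A has 4 voxels, B those 4 plus 4 more
    assert dice(a, b) == pytest.approx(2 * 4 / (4 + 8))
    with pytest.raises(InputError):
        dice(a, np.zeros((3, 3, 3), dtype=bool))


def test_majority_filter_removes_speckle(clean_phantom, clean_thresholds):
    spec, _, truth, _ = clean_phantom
    noisy_ct, _ = generate_ct_phantom(replace(spec, noise_sigma=400.0))
    labels = segment_vessel(to_hounsfield(noisy_ct), clean_thresholds)
    cleaned = majority_filter(labels)
    media_truth = truth.label_volume.mask(Layer.MEDIA)
    assert dice(cleaned.mask(Layer.MEDIA), media_truth) >= dice(labels.mask(Layer.MEDIA), media_truth)
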