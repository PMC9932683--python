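"""Shared fixtures: small phantoms sized for fast, exact checks."""

from dataclasses import replace

import numpy as np
import pytest

from vesselct import PhantomSpec, generate_ct_phantom, thresholds_from_spec, to_hounsfield


def small_spec(**overrides) -> PhantomSpec:
    """A half-scale vessel on a compact grid; override fields as needed."""
    spec = PhantomSpec(
        grid_shape=(16, 72, 72),
        lumen_radius=60.0,
        intima_outer_radius=78.0,
        media_outer_radius=150.0,
        adventitia_outer_radius=180.0,
    )
    return replace(spec, **overrides)


@pytest.fixture
def clean_spec() -> PhantomSpec:
    """Noise-free, blur-free small phantom spec."""
    return small_spec(noise_sigma=0.0, blur_sigma=0.0)


@pytest.fixture
def clean_phantom(clean_spec):
    """(spec, CTVolume, PhantomTruth, HUVolume) of a noiseless phantom."""
    ct, truth = generate_ct_phantom(clean_spec)
    return clean_spec, ct, truth, to_hounsfield(ct)


@pytest.fixture
def clean_thresholds(clean_spec):
    return thresholds_from_spec(clean_spec)
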