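"""Generate a synthetic stained-vessel CT phantom and export it as DICOM.

The phantom is a layered cylinder (lumen / intima / media / adventitia) in an
ethanol bath.  The media carries a radial collagen gradient (fraction 0.2 at
its inner boundary to 0.6 at its outer boundary) that the stain converts into
an HU gradient.
"""

import tempfile
from pathlib import Path

from vesselct import PhantomSpec, generate_ct_phantom, to_hounsfield, write_dicom_series

spec = PhantomSpec(grid_shape=(32, 128, 128), rng_seed=1)
ct, truth = generate_ct_phantom(spec)
hu = to_hounsfield(ct)

print(f"grid {ct.shape}, voxel {spec.voxel_size} um isotropic")
for layer, vol in truth.layer_volumes_mm3.items():
    mask = truth.label_volume.mask(layer)
    print(f"  {layer.name:<11} {vol:.5f} mm^3   mean HU {hu.hu[mask].mean():7.1f}")
print(f"tissue volume: {truth.tissue_volume_mm3:.5f} mm^3")

with tempfile.TemporaryDirectory() as d:
    files = write_dicom_series(ct, Path(d) / "series")
    print(f"wrote {len(files)} DICOM slices (RescaleSlope={ct.rescale_slope}, "
          f"RescaleIntercept={ct.rescale_intercept})")

# The per-layer mean HU values are what threshold segmentation exploits: the
# bath/lumen sit far below the tissue layers, and the media's mean includes
# the collagen contrast on top of its base attenuation.
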