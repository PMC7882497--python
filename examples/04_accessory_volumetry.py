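"""Accessory measurements: region growing and ventricle splitting.

Grows a Meckel's-cave blob from a seed point by intensity similarity and
splits a synthetic lateral-ventricle mask into anterior/posterior
compartments at the midpoint of its extent.
"""

import numpy as np

from hydromorph import accessory, imaging, phantom

spec = phantom.PhantomSpec()
intensity, labels, truth = phantom.make_head_phantom(spec)

seed = np.argwhere(labels.values == 8)[0]
blob = accessory.region_grow(intensity, [seed], tolerance=30.0)
vol = accessory.mask_volume(blob)
print(f"Meckel's cave: grown {vol:.0f} mm^3 from one seed "
      f"(analytic sphere volume {truth.meckel_volume_mm3[0]:.0f} mm^3)")

g = np.meshgrid(*[np.arange(41) - 20] * 3, indexing="ij")
lv = ((g[0] / 6) ** 2 + (g[1] / 14) ** 2 + (g[2] / 5) ** 2 <= 1)
lv_vol = imaging.VoxelVolume(lv.astype(np.uint8))
anterior, posterior = accessory.split_lv(lv_vol, axis=1)
print(f"lateral ventricle: anterior {anterior:.0f} mm^3, "
      f"posterior {posterior:.0f} mm^3 "
      f"(total {accessory.mask_volume(lv_vol):.0f} mm^3; the symmetric "
      "phantom splits evenly)")
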