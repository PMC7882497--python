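"""Segment and quantify the optic nerves of a phantom.

The nerve is found inside a rough ROI by intensity windowing (largest
26-connected object), its skeleton's longest path becomes the
centerline, and length / caliber / arch-to-chord tortuosity are read
from it.  The phantom's nerves are sinusoidal tubes, so each measure has
an analytic truth.
"""

from hydromorph import optic_nerve, phantom

spec = phantom.PhantomSpec(noise_sd=5.0, rng_seed=1)
intensity, labels, truth = phantom.make_head_phantom(spec)

metrics = {}
for i, side in enumerate(("left", "right")):
    mask = optic_nerve.segment_on(intensity, truth.roi_on[i],
                                  intensity_low=22.5, intensity_high=70.0)
    metrics[side] = optic_nerve.on_metrics(mask, side=side)

mean = optic_nerve.bilateral_average(metrics["left"], metrics["right"])

print(f"generated nerve: arc length {truth.on_arc_length_mm[0]:.1f} mm, "
      f"diameter {truth.on_diameter_mm[0]:.1f} mm, "
      f"arch-to-chord ratio {truth.on_arch_chord_ratio[0]:.3f}")
for side, m in (*metrics.items(), ("bilateral mean", mean)):
    print(f"{side:>14}: length {m.length_mm:5.1f} mm, width {m.width_mm:.2f} mm, "
          f"ratio {m.tortuosity_ratio:.3f}")
print("A ratio of 1.0 is a perfectly straight nerve; straightening "
      "(ratio toward 1) is the deformation associated with enlarged CSF spaces.")
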