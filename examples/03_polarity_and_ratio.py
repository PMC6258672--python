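"""Render a fluorescence stack, measure ROI densities and planar polarity.

The generator paints Myosin-II line densities (DV-polarized, amplitude 2)
into a noisy z-stack; the quantification recovers the densities from
5-px junctional ROIs after focus selection and background subtraction.
"""

import numpy as np

from epimech import quantify, synth

cfg = synth.SyntheticConfig(n_cells=60, domain_px=256, image_px=256, seed=4)
net, truth = synth.generate_equilibrium_network(cfg)
dens = synth.assign_intensities(net, truth, cfg)
stack, labels = synth.render_images(net, dens["myosin"], cfg)

img, focus = quantify.preprocess_stack(
    stack, background_radius=20, return_focus=True
)
rois = quantify.extract_rois(net, img.shape, labels=labels)
measured = quantify.roi_density(img, rois)

angles = {j: net.junctions[j].angle for j in measured.junction_density}
finite = {
    j: v for j, v in measured.junction_density.items() if np.isfinite(v)
}
profile = quantify.polarity_profile(finite, angles, mode="DV/AP")

print(f"focus plane selected: {focus} (ground truth {cfg.focus_plane})")
print(f"junctions measured:   {len(finite)} "
      f"({len(rois.empty_junctions)} too short for an ROI)")
print("ALD per 15-degree bin:", np.round(profile.ald, 3))
print(f"PCP amplitude (DV/AP): {profile.pcp:.3f} (generator polarity 2.0, "
      "diluted by the tension weighting of short DV junctions)")
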