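"""Quantify a synthetic immunostained section layer by layer.

Renders a DAB-stained slide with a known nonlinear laminar plaque
profile, then runs the quantification chain — color deconvolution,
moment-preserving thresholding, 2D laminar segmentation between the
boundary polylines, and per-layer positive-pixel fractions — and
compares the recovered densities with the slide's ground truth.
"""

import numpy as np

from laminaprof import histo, laminar, synth

spec = synth.SlideSpec(stain="dab",
                       layer_targets=(0.02, 0.05, 0.10, 0.15, 0.15, 0.12),
                       seed=5)
rgb, truth, boundaries = synth.render_slide(spec)
print(f"rendered {rgb.shape[1]}x{rgb.shape[0]} slide, stain '{spec.stain}' "
      f"with hematoxylin counterstain")

img = histo.StainImage(rgb.astype(float), stains=["dab", "hematoxylin"])
channels = histo.color_deconvolve(img)
threshold, positive = histo.moment_threshold(channels["dab"])
print(f"moment-preserving threshold on the DAB channel: {threshold:.3f} OD")

region = np.zeros(rgb.shape[:2], bool)
region[spec.band_top_row : spec.band_bottom_row + 1] = True
layers, _ = laminar.layering_2d(region, boundaries["pial"], boundaries["wm"], K=8)
density = histo.layer_density(positive, layers, "dab", "slide01")

merged = density.merge(truth, on="layer")
print("\nlayer  recovered  truth")
for _, row in merged.iterrows():
    print(f"  {row.layer:>3}   {row.positive_fraction:7.3f}  "
          f"{row.realized_fraction:6.3f}")
err = (merged.positive_fraction - merged.realized_fraction).abs().max()
print(f"\nmax |recovered - truth| = {err:.4f} "
      "(the full chain reproduces the laminar burden profile)")
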