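"""Build a cortical-ribbon phantom and segment it into six layers.

Generates a spherical-shell phantom whose tensors realize a known
laminar MD/FA profile, runs the equidistant laminar segmentation, and
compares the computed lamina labels with the generator's ground truth.
"""

import numpy as np

from laminaprof import laminar, synth

spec = synth.PhantomSpec(
    inner_radius_mm=10, outer_radius_mm=13, voxel_size_mm=(0.4, 0.4, 0.4)
)
gm, wm, roi_atlas, tensors, truth = synth.make_phantom(spec)
print(f"phantom grid {gm.values.shape}, {int(gm.mask.sum())} GM voxels, "
      f"{spec.roi_count} ROIs")

pial, wm_boundary = laminar.extract_boundaries(gm.mask, wm.mask)
depth = laminar.compute_depth(gm.mask, pial, wm_boundary, gm.voxel_size_mm)
laminae = laminar.assign_laminae(depth, K=8)
layers = laminar.retain_layers(laminae, K=8)

print(f"lamina labels present: {sorted(np.unique(laminae[gm.mask]))}")
print(f"retained layers (I-VI): {sorted(np.unique(layers[layers > 0]))}")

agreement = (laminae[gm.mask] == truth["lamina"][gm.mask]).mean()
print(f"agreement with ground-truth laminae: {agreement:.1%}")
print("(disagreements sit on lamina bin edges; they shrink as the ribbon "
      "is sampled more finely)")
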