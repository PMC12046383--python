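# laminaprof

Layer-resolved cortical microstructure profiling for ex vivo MRI–histology
studies.

The neocortex is a laminated sheet: its six cytoarchitectonic layers differ
in cell and myelin density, and diffusion MRI at sub-millimetre resolution
can resolve those differences as depth profiles of the tensor metrics.
`laminaprof` implements the full analysis chain for studies that relate
laminar diffusivity changes to pathology burden (e.g. amyloid-β plaques in
early Alzheimer-spectrum cases):

1. **Equidistant laminar segmentation** — every grey-matter voxel gets a
   normalized cortical depth `d = D_pial / (D_pial + D_WM)` from Euclidean
   distance transforms to the pial and white-matter boundary voxel sets;
   binning `d` into K = 8 equal-width laminae and discarding the outermost
   and innermost (partial-volume-dominated) laminae leaves six layers I–VI.
   The same machinery layers 2D histological sections between hand-drawn
   boundary polylines.
2. **Diffusion tensor profiling** — ordinary least-squares log-linear fit of
   `S(g, b) = S0 · exp(−b · gᵀDg)`, eigenvalue metrics
   `MD = (λ₁+λ₂+λ₃)/3`, `AD = λ₁`, `RD = (λ₂+λ₃)/2`,
   `FA = √(3/2) · √Σ(λᵢ−MD)² / √Σλᵢ²`, per-subject normalization by the
   cortex mean (mFA, mMD, …), and reduction to (subject × ROI × layer)
   mean profiles with a parcel-thickness QC filter (|Δthickness| < 0.5 mm).
3. **Histology quantification** — Ruifrok–Johnston color deconvolution of
   brightfield RGB into stain density channels, Tsai-style
   moment-preserving binarization, and per-layer positive-pixel fractions.
4. **Statistics** — covariate-residualized (age, sex, thickness, PMI,
   fixation time) two-sample t-tests between amyloid-negative and
   amyloid-positive groups per layer and per (ROI, layer) cell with
   Benjamini–Hochberg FDR across the 28 × 6 = 168-test family; a linear
   mixed model `value ~ age + sex + Braak + amyloid + (1 | subject)`;
   matched-pair laminar ΔMD profiles; and layer-wise Spearman correlation
   with exact permutation p-values at n = 6.
5. **Synthetic ground truth** — shell/slab DWI phantoms with radially
   oriented tensors realizing a prescribed laminar MD/FA profile, a
   15-subject cohort generator (4 HC, 3 PART, 8 amyloid-positive) with
   configurable injected laminar effects, and Beer–Lambert-rendered
   stained slides with exact per-layer positive fractions — so every stage
   is testable end to end against known truth.

## Worked example

`examples/` contains one narrative script per capability. For instance,
simulating a noisy acquisition of a laminar phantom and recovering its
depth profile (`examples/02_dti_layer_profile.py`):

```
synthesized 80 volumes (20 b0 + 60 DWI)

per-layer means (pial-most layer I first):
  layer   I: MD 3.994e-04 mm^2/s (truth 4.000e-04), FA 0.128
  layer  II: MD 3.700e-04 mm^2/s (truth 3.700e-04), FA 0.154
  layer III: MD 3.400e-04 mm^2/s (truth 3.400e-04), FA 0.190
  layer  IV: MD 3.099e-04 mm^2/s (truth 3.100e-04), FA 0.246
  layer   V: MD 2.800e-04 mm^2/s (truth 2.800e-04), FA 0.304
  layer  VI: MD 2.499e-04 mm^2/s (truth 2.500e-04), FA 0.382
```

MD falls and FA rises from the pial surface toward white matter — the
canonical laminar pattern — and the per-layer means recover the
generating profile to a fraction of a percent at SNR 30 Rician noise.

The group analysis (`examples/04_group_statistics.py`) injects a +10% MD
elevation into layers II/III of the amyloid-positive group and prints the
pooled per-layer t-tests; the injected layers come out with negative t
(amyloid-positive group higher, with the amyloid-negative group listed
first) while unaffected layers stay null:

```
pooled per-layer MD t-tests:
layer         t        p
    I  0.885468 0.391989
   II -2.351495 0.035128
  III -2.398158 0.032196
   IV  0.894794 0.387165
    V  0.690740 0.501877
   VI  0.560678 0.584552
```

The full pipeline (simulate → layer → dti → histo → stats) runs from one
YAML-able configuration via `laminaprof.io.run_pipeline`
(`examples/05_full_pipeline.py`), writing CSV products and a provenance
log; reruns are byte-identical.

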