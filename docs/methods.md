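# Methods

This note documents the models, conventions, and numerical choices behind
`laminaprof`, and what the synthetic-data validation does and does not
establish about real specimens.

## Equidistant laminar segmentation

The cortical ribbon is bounded by the pial (GM–CSF) and white-matter
(GM–WM) surfaces. Both are represented as *voxel sets inside the GM mask*:
the WM boundary is every GM voxel face-adjacent (6-connected in 3D,
4-connected in 2D) to WM, and the pial boundary every GM voxel
face-adjacent to anything that is neither GM nor WM. Dilating the
neighbouring compartment by one voxel and intersecting with GM yields the
same sets; we chose face connectivity as the tightest structuring element
(the choice only shifts boundary membership by sub-voxel amounts).

Depth is the distance fraction `d = D_pial / (D_pial + D_WM)` with both
distances computed in millimetres by a sampled Euclidean distance
transform (anisotropic voxels supported). Conventions:

- voxels in the pial set get `d = 0`, in the WM set `d = 1`;
- voxels in *both* sets (one-voxel ribbons) get `d = 0.5`;
- laminae are `min(floor(d·K) + 1, K)` — equal-width bins with ties at bin
  edges going to the deeper lamina and `d = 1` clamped into lamina K;
- with K = 8, laminae 1 and K are discarded and laminae 2..7 relabelled
  I..VI (I pial-most). The discarded laminae absorb the partial-volume
  voxels hugging both surfaces.

Equidistant (not equipotential/Laplacian, not equivolume) layering is
deliberate: it is the simplest definition, it is exact on slabs, and it is
the definition the rest of the pipeline assumes. On a slab the computed
depth is exactly `i/(n−1)` for GM row `i`, which the tests verify against
a brute-force minimum-distance oracle.

Parcel thickness for QC is estimated as the mean of `D_pial + D_WM` over a
parcel's GM voxels. On a sampled grid this is a centre-to-centre measure
that underestimates the geometric thickness by about one voxel; with the
default 0.5 mm acceptance band around the reference value this bias is
immaterial for the ribbon geometries involved (~3 mm cortex at ≤ 0.5 mm
voxels), and using the same estimator for subject and reference values
cancels it entirely when references are derived from the same machinery.

**Discretization of depth.** The distance transform measures distance to
the nearest boundary *voxel centre* of a jagged discrete surface, so
depth carries noise of roughly a quarter voxel at each end. Lamina labels
computed from it therefore disagree with an analytic ground truth only at
bin edges, and only by one lamina; the fraction of agreeing voxels exceeds
95% once the ribbon spans at least ~15 voxels (e.g. a 3 mm ribbon at 0.2 mm
sampling) and approaches 100% on slabs. The shell phantom's ground-truth
depth is defined on the boundary-voxel-centre scale (half a voxel inside
each surface) so that truth and pipeline measure the same quantity.

## Diffusion tensor model

The fit is ordinary least squares on `ln S` against the standard 7-column
design `[1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz]`,
solved for all voxels at once with a pseudoinverse. Choices:

- OLS rather than WLS/NLLS: the simplest defensible default for
  high-SNR ex vivo data; all volumes (including every b0) enter the
  regression directly rather than via a separate b0 average.
- Non-positive signals are replaced by a tiny epsilon *individually*
  before the log (positive signals are never clipped, however small) and
  the voxel is flagged; voxels with no positive signal at all are
  excluded from the fitted mask.
- A rank-deficient design (collinear directions) raises immediately.
- Negative eigenvalues from noisy fits are kept in the FA/MD arithmetic
  (the voxel is flagged); clipping would bias layer means.

Metrics follow the eigenvalue definitions (λ₁ ≥ λ₂ ≥ λ₃): MD the mean,
AD = λ₁, RD the mean of the two smaller, FA the normalized eigenvalue
dispersion with FA(0-tensor) defined as 0. `MD = (AD + 2·RD)/3` holds
identically. Normalized metrics divide by the map mean over the *cortex
mask*, taken as the union of retained layers I–VI — the excluded laminae
are also excluded from the normalizing mean, keeping the normalization
consistent with the analysis mask. Noiseless synthesize→fit round trips
recover tensor components to ~1e−18 mm²/s, i.e. to solver precision.

## Histology quantification

Brightfield staining follows Beer–Lambert: per-channel optical density
`OD_c = −log₁₀(max(I_c, 1)/I0)` is linear in stain amounts, so densities
are `OD · M⁻¹` for a stain matrix M of unit-norm OD row vectors.
Presets (H, E, DAB from the standard deconvolution literature, plus an
approximate Luxol-Fast-Blue-style blue-absorber vector) are starting
points only — stain vectors drift between batches and should be
overridden per study. A two-stain matrix is completed with the orthogonal
complement as the residual channel; which channel carries the target
stain is an explicit argument, never hard-coded.

**Moment-preserving threshold.** The binarization picks the grey-level
split whose two-level representative image preserves the channel's first
three grey-level moments: for each candidate split the representative
pair (z₀, z₁) preserving m₁ and m₂ exactly is solved in closed form, and
the split minimizing the residual third-moment mismatch is chosen (lowest
split on ties; pixels at or above the threshold are positive). Away from
discretization ties this coincides with the classical continuous solution
that thresholds at the p₀-fractile of the histogram; enumerating the
≤ 256 candidate splits costs nothing and makes the discrete choice
optimal by the moment-preservation criterion itself, rather than
dependent on a cumulative-histogram rounding convention. Channels are
quantized to 256 bins (the method is histogram-based); the threshold is
reported on the original channel scale. Thresholding is global per
channel by default — the locality window of "locally thresholded"
protocols is rarely reported; a tiled per-window variant would be a thin
wrapper and was not needed for the validation targets.

Layer density is the positive-pixel fraction within each retained layer
band of the 2D laminar segmentation, computed between the CSF–GM and
WM–GM boundary polylines. Fractions are computed on the deconvolved,
thresholded target channel, following the deconvolve→threshold→count
sequence.

## Statistics

- **Residualization**: pooled OLS of the metric on [1, age, sex(0/1),
  thickness, PMI, fixation time] *without* a group term, then a Student
  pooled-variance two-sample t-test on the residuals
  (amyloid-negative listed first, so a negative t means the
  amyloid-positive group is higher). Both granularities are emitted: per
  (ROI, layer) cell and per layer pooled over ROIs (subjects averaged
  across ROIs first). Caveat, measured in simulation: when a covariate is
  itself group-dependent (e.g. cortical thinning in the amyloid-positive
  group), regress-out-then-test partially absorbs the group effect and
  becomes conservative — size falls well below nominal and power drops
  several-fold. The size/power calibration therefore uses cohorts with
  group-exchangeable covariates, which is also the only null under which
  "size" is well defined. An ANCOVA-style design is the standard remedy
  when covariates and group are confounded.
- **FDR**: Benjamini–Hochberg step-up, `q(i) = min_{j≥i} p(j)·m/j`
  clipped at 1; the family is the 168 ROI × layer tests per metric.
- **Mixed model**: `value ~ age + sex + Braak + amyloid` with a random
  intercept per subject, REML. Per-layer fits pool a subject's ROIs
  (random intercept estimable); per-(ROI, layer) fits have one
  observation per subject and degrade to OLS with an explicit
  `ols_fallback` flag, as does any singular REML fit. Reported Wald
  statistics are asymptotic; with a between-subject covariate and 15
  subjects the effective reference is a t with ~10 degrees of freedom,
  so |t| ≥ 2 has a true level near 7–8%, not 4.6% — the null-calibration
  test accounts for this.
- **ΔMD**: cell-wise case − matched-control differences with the
  pairing declared explicitly (age/sex matching is a judgement call,
  not an algorithm).
- **Spearman across layers**: average-rank rho; for n ≤ 8 the two-sided
  p is exact, by full enumeration of the n! pairings (at n = 6 a perfect
  correlation gives p = 2/720 ≈ 0.00278); beyond that the asymptotic
  t-approximation is used.

## Synthetic data: what it emulates, and what it does not

**Phantoms.** The default geometry is a spherical shell (closed surface,
no edge artifacts; a slab is kept for exact analytic tests). Every GM
tensor is axially symmetric and radially oriented; given layer targets
(MD, FA) the eigenvalues come from the closed form
`Δ = √3·MD·FA / √(1 − ⅔·FA²)`, `λ∥ = MD + 2Δ/3`, `λ⊥ = MD − Δ/3`.
Default laminar profiles — MD falling linearly from 0.40 to
0.25 × 10⁻³ mm²/s and FA rising from 0.10 to 0.38, pial to WM — encode
the canonical fixed-cortex depth pattern at plausible ex vivo
magnitudes. ROIs are equal angular (shell) or in-plane (slab) sectors,
4 by default, standing in for atlas parcels that in real studies arrive
as inputs.

**Protocol.** 20 b0 volumes plus 60 unique directions at
b = 6000 s/mm², matching a high-b ex vivo acquisition. Directions are a
deterministic spherical Fibonacci lattice — equally well spread as
electrostatic-repulsion sets but reproducible without an optimizer.
Noise is Rician by default (magnitude MRI) with SNR ≡ S0/σ, default 30;
the source acquisition's actual SNR is unknown, so this default is a
plausible setting, not a claim. At SNR 30 the per-layer MD bias is under
3% and the laminar ordering of all six layer means is preserved.

**Cohort.** Default sizes 4 HC + 3 PART + 8 amyloid-positive with the
published per-case covariates (age, sex, PMI, fixation time, Braak and
amyloid stages) as the default table; other sizes sample from per-group
distributions fitted to it. Cortical thickness is generated
group-independent by default (N(2.85, 0.15) mm) so the no-effect cohort
is exchangeable; an optional `thickness_gap_mm` reproduces
amyloid-associated thinning for sensitivity experiments. The injected
effect is multiplicative on MD per (group, layer[, ROI]) — default +10%
in layers II and III of the amyloid-positive group; between-subject
(5%), between-ROI (2%) and per-cell (3%) lognormal variability set the
noise floor. The fast "profile" mode draws (ROI × layer) tables
directly; "imaging" mode synthesizes a full phantom + DWI per subject.

**Slides.** One target stain per rendered slide (plus a light uniform
counterstain), blobs placed per retained layer band and trimmed/padded to
the target pixel count exactly, RGB from Beer–Lambert mixing quantized to
8 bits. Truth tables count the ground-truth mask, so the
render→deconvolve→threshold→count chain is checked end to end (recovered
fractions within 0.02, typically exact).

**Limits.** The generators do not simulate gyral folding, partial-volume
mixing, registration error, fixation gradients, non-monoexponential
(DW-SSFP-specific) signal behaviour, spatially varying stain uptake, or
cell-level morphology. Passing tests therefore establish the
*correctness of the computations* on data obeying the stated models at
realistic noise levels — not that real tissue obeys those models, nor
that the small-cohort statistics would be well powered on real specimens.

## Determinism and sizes

Every stochastic operation takes an explicit seed; identical
specifications give bit-identical volumes, images and CSVs. The
validation battery runs at deliberately small problem sizes — 100-voxel
tensor oracles, ~30³–70³ phantom grids (one 134³ grid for the fine-shell
lamina check), 400 × 300 slides, 200-replicate calibration loops — chosen
so the whole suite and the acceptance script each complete in about a
minute on a single CPU while leaving every tolerance comfortably
non-trivial.
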