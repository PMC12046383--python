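"""Detect a laminar group effect in a simulated case-control cohort.

Builds a 15-subject cohort (4 controls, 3 tauopathy, 8 amyloid-positive)
with a +10% MD elevation injected into layers II and III of the
amyloid-positive group, then runs the full statistical battery:
covariate-residualized two-sample t-tests per layer with BH-FDR, the
staging mixed model, matched-pair delta-MD profiles, and a layer-wise
Spearman correlation against a stain density profile.
"""

import numpy as np

from laminaprof import stats, synth

cohort_spec = synth.CohortSpec(
    effect_spec={("AbPos", "II"): 1.10, ("AbPos", "III"): 1.10}, seed=42
)
out = synth.make_cohort(cohort_spec)
cov, profiles = out["covariates"], out["profiles"]
print(f"cohort: {cov.groupby('group').size().to_dict()} "
      f"({(cov.ab_status == 'positive').sum()} amyloid-positive)")

result = stats.group_ttest(profiles, cov, metric="MD")
pooled = result[result.roi == "pooled"].set_index("layer")
q, sig = stats.fdr_bh(pooled["p"].to_numpy())
print("\npooled per-layer t-tests (amyloid-negative minus amyloid-positive):")
for (layer, row), qv in zip(pooled.iterrows(), q):
    mark = " *" if qv <= 0.05 else ""
    print(f"  layer {layer:>3}: t = {row.t:6.2f}, p = {row.p:.4f}, q = {qv:.4f}{mark}")
print("negative t in layers II/III: the amyloid-positive group has the "
      "higher MD exactly where the effect was injected")

lmm = stats.fit_stage_lmm(profiles, cov, metric="MD")
amy = lmm[(lmm.term == "amyloid") & (lmm.layer == "II")].iloc[0]
print(f"\nmixed model, layer II amyloid-stage slope: "
      f"coef = {amy.coef:.2e}, t = {amy.t:.2f}, p = {amy.p:.4f}")

delta = stats.delta_profile(profiles, {"ad1": "HC3", "ad3": "HC2"}, metric="MD")
by_layer = delta.groupby("layer")["delta"].mean()
print("\nmatched-pair delta-MD (case - control), mean over pairs/ROIs:")
print("  " + ", ".join(f"{l}: {by_layer[l]:.2e}" for l in
                       ("I", "II", "III", "IV", "V", "VI")))

# correlate the delta profile with a plaque density profile that, like
# the injected MD effect, is concentrated in layers II/III
ab_density = np.array([0.03, 0.14, 0.15, 0.06, 0.04, 0.03])
rho, p = stats.spearman_layers(
    by_layer[["I", "II", "III", "IV", "V", "VI"]].to_numpy(), ab_density
)
print(f"\nSpearman(delta-MD, plaque density) across 6 layers: "
      f"rho = {rho:.2f}, exact p = {p:.4f}")
print("a positive rank correlation links the laminar MD elevation to the "
      "laminar plaque burden, mirroring the MRI-histology comparison")
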