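"""Residualized group tests, BH-FDR, mixed models, deltas, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from laminaprof import stats, synth
from laminaprof.dti import LAYER_NAMES


def toy_cohort(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(n)],
            "group": ["HC"] * (n // 2) + ["AbPos"] * (n - n // 2),
            "age": rng.integers(50, 90, n),
            "sex": rng.choice(["M", "F"], n),
            "pmi_min": rng.integers(200, 1000, n),
            "ft_days": rng.integers(30, 60, n),
            "thickness_mm": rng.normal(3.0, 0.2, n).round(3),
            "braak": rng.integers(0, 4, n),
            "amyloid": [0] * (n // 2) + list(rng.integers(1, 3, n - n // 2)),
        }
    ).assign(ab_status=lambda d: np.where(d.amyloid >= 1, "positive", "negative"))


def toy_profiles(cohort, values_by_subject, layer="II", roi=1, metric="MD"):
    rows = []
    for s, v in zip(cohort["subject"], values_by_subject):
        rows.append({"subject": s, "roi": roi, "layer": layer,
                     "metric": metric, "value": v, "n_voxels": 100})
    return pd.DataFrame(rows)


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        cohort = toy_cohort()
        values = 2.0 * cohort["age"].to_numpy(float)
        res = stats.residualize(values, cohort)
        assert np.abs(res).max() < 1e-10

    def test_constant_covariates_dropped_residuals_centered(self):
        cohort = toy_cohort()
        cohort["ft_days"] = 40
        rng = np.random.default_rng(1)
        values = rng.normal(size=len(cohort))
        res = stats.residualize(values, cohort, covariates=("ft_days",))
        assert np.allclose(res, values - values.mean())

    def test_residual_mean_zero(self):
        cohort = toy_cohort()
        rng = np.random.default_rng(2)
        res = stats.residualize(rng.normal(size=len(cohort)), cohort)
        assert res.mean() == pytest.approx(0.0, abs=1e-12)

    def test_collinear_covariate_named(self):
        cohort = toy_cohort()
        cohort["pmi_min"] = 2 * cohort["age"]
        with pytest.raises(ValueError, match="collinear covariate"):
            stats.residualize(np.ones(len(cohort)), cohort,
                              covariates=("age", "pmi_min"))

    def test_group_effect_survives_residualization(self):
        # values = beta*age + group shift + noise: with covariates
        # orthogonal to the group contrast the residualized group
        # difference estimates the injected shift without attenuation
        rng = np.random.default_rng(3)
        diffs = []
        for rep in range(100):
            cohort = toy_cohort(n=20, seed=rep)
            g = (cohort.group == "AbPos").to_numpy(float)
            gc = g - g.mean()
            for col in ("age", "pmi_min", "ft_days", "thickness_mm"):
                v = cohort[col].to_numpy(float)
                cohort[col] = v - gc * (v @ gc) / (gc @ gc)
            shift = 0.5 * g
            values = 0.02 * cohort.age.to_numpy(float) + shift + rng.normal(0, 0.2, 20)
            res = stats.residualize(
                values, cohort,
                covariates=("age", "pmi_min", "ft_days", "thickness_mm"),
            )
            diffs.append(res[g == 1].mean() - res[g == 0].mean())
        assert np.mean(diffs) == pytest.approx(0.5, abs=0.05)


class TestGroupTtest:
    def test_identical_groups_t_zero_p_one(self):
        cohort = toy_cohort()
        prof = toy_profiles(cohort, np.tile([1.0, 2.0, 3.0], 4))
        # same values in both groups
        prof["value"] = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 2)
        res = stats.group_ttest(prof, cohort, residualize_values=False)
        row = res[res.roi != "pooled"].iloc[0]
        assert row.t == pytest.approx(0.0, abs=1e-12)
        assert row.p == pytest.approx(1.0)

    def test_matches_textbook_t_without_covariates(self):
        cohort = toy_cohort()
        rng = np.random.default_rng(4)
        vals = rng.normal(size=len(cohort))
        prof = toy_profiles(cohort, vals)
        res = stats.group_ttest(prof, cohort, residualize_values=False)
        neg = vals[(cohort.ab_status == "negative").to_numpy()]
        pos = vals[(cohort.ab_status == "positive").to_numpy()]
        t_ref, p_ref = sps.ttest_ind(neg, pos)
        row = res[res.roi != "pooled"].iloc[0]
        assert row.t == pytest.approx(t_ref, rel=1e-12)
        assert row.p == pytest.approx(p_ref, rel=1e-12)

    def test_sign_convention_abpos_higher_gives_negative_t(self):
        cohort = toy_cohort()
        vals = np.where(cohort.ab_status == "positive", 10.0, 1.0)
        vals = vals + np.linspace(0, 0.1, len(vals))
        prof = toy_profiles(cohort, vals)
        res = stats.group_ttest(prof, cohort, residualize_values=False)
        assert (res.t < 0).all()

    def test_168_comparisons_with_28_rois(self):
        cohort = toy_cohort(n=10)
        rng = np.random.default_rng(5)
        rows = []
        for roi in range(1, 29):
            for layer in LAYER_NAMES:
                for s in cohort.subject:
                    rows.append({"subject": s, "roi": roi, "layer": layer,
                                 "metric": "MD",
                                 "value": rng.normal(), "n_voxels": 10})
        prof = pd.DataFrame(rows)
        res = stats.group_ttest(prof, cohort)
        cellwise = res[res.roi != "pooled"]
        assert len(cellwise) == 168
        assert len(res[res.roi == "pooled"]) == 6

    def test_small_group_cell_skipped(self):
        cohort = toy_cohort()
        prof = toy_profiles(cohort, np.arange(len(cohort), dtype=float))
        prof = prof[prof.subject != "s11"]
        drop = prof.subject != "s10"
        prof = prof[drop | (prof.subject == "s10")]
        cohort_small = cohort[cohort.subject.isin(["s0", "s1", "s2", "s6"])]
        prof_small = prof[prof.subject.isin(cohort_small.subject)]
        res = stats.group_ttest(prof_small, cohort_small, residualize_values=False)
        assert res.empty


class TestFdrBH:
    def test_single_p_unchanged(self):
        q, _ = stats.fdr_bh([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_hand_computed_example(self):
        q, sig = stats.fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)
        assert sig.all()

    def test_all_ones(self):
        q, sig = stats.fdr_bh([1.0] * 5)
        assert (q == 1.0).all() and not sig.any()

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 40))
            q, sig = stats.fdr_bh(p, alpha=0.05)
            rej, q_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert np.allclose(q, q_ref)
            assert np.array_equal(sig, rej)

    def test_rejection_set_matches_step_up_definition(self):
        rng = np.random.default_rng(8)
        alpha = 0.05
        for _ in range(20):
            p = rng.uniform(size=30) ** 2
            _, sig = stats.fdr_bh(p, alpha=alpha)
            # brute force: largest i with p_(i) <= i*alpha/m
            srt = np.sort(p)
            ks = np.nonzero(srt <= (np.arange(1, 31) * alpha / 30))[0]
            expected = np.zeros(30, bool)
            if len(ks):
                expected = p <= srt[ks[-1]]
            assert np.array_equal(sig, expected)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            stats.fdr_bh([0.1, np.nan])


class TestStageLmm:
    def test_amyloid_coefficient_recovered(self):
        rng = np.random.default_rng(10)
        cohort = toy_cohort(n=15, seed=1)
        rows = []
        beta_amyloid = 0.05
        for s, amy, age in zip(cohort.subject, cohort.amyloid, cohort.age):
            subj_eff = rng.normal(0, 0.005)
            for roi in range(1, 5):
                rows.append({"subject": s, "roi": roi, "layer": "III",
                             "metric": "MD",
                             "value": 1.0 + beta_amyloid * amy
                             + 0.001 * age + subj_eff + rng.normal(0, 0.002),
                             "n_voxels": 10})
        prof = pd.DataFrame(rows)
        fit = stats.fit_stage_lmm(prof, cohort, metric="MD")
        amy = fit[(fit.term == "amyloid") & (fit.layer == "III")]
        assert amy.model.iloc[0] == "lmm_reml"
        assert amy.coef.iloc[0] == pytest.approx(beta_amyloid, rel=0.10)

    def test_per_cell_fit_degrades_to_ols(self):
        cohort = toy_cohort(n=15, seed=2)
        rng = np.random.default_rng(11)
        prof = toy_profiles(cohort, rng.normal(size=len(cohort)))
        fit = stats.fit_stage_lmm(prof, cohort, metric="MD", per_layer=False)
        assert (fit.model == "ols_fallback").all()

    def test_constant_stage_column_errors(self):
        cohort = toy_cohort()
        cohort["braak"] = 2
        prof = toy_profiles(cohort, np.arange(len(cohort), dtype=float))
        with pytest.raises(ValueError, match="braak"):
            stats.fit_stage_lmm(prof, cohort)


class TestDeltaProfile:
    def _profiles(self):
        rows = []
        for s, base in (("ad1", 1.0), ("HC3", 1.0)):
            for roi in (1, 2):
                for i, layer in enumerate(LAYER_NAMES):
                    rows.append({"subject": s, "roi": roi, "layer": layer,
                                 "metric": "MD", "value": base + 0.1 * i,
                                 "n_voxels": 5})
        return pd.DataFrame(rows)

    def test_identical_profiles_zero_delta(self):
        delta = stats.delta_profile(self._profiles(), {"ad1": "HC3"})
        assert np.allclose(delta["delta"], 0.0)
        assert (delta["matched_hc"] == "HC3").all()

    def test_uniform_offset_recovered(self):
        prof = self._profiles()
        prof.loc[prof.subject == "ad1", "value"] += 0.1
        delta = stats.delta_profile(prof, {"ad1": "HC3"})
        assert np.allclose(delta["delta"], 0.1)

    def test_injected_layer_effect_visible_in_deltas(self):
        spec = synth.CohortSpec(subject_sd=0.0, cell_noise_sd=0.0, roi_sd=0.0, seed=3)
        out = synth.make_cohort(spec)
        delta = stats.delta_profile(out["profiles"], {"ad1": "HC1"})
        by_layer = delta.groupby("layer")["delta"].mean()
        base = dict(zip(LAYER_NAMES, synth.DEFAULT_LAYER_MD))
        assert by_layer["II"] == pytest.approx(0.10 * base["II"], rel=1e-6)
        assert by_layer["I"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_pair_errors(self):
        with pytest.raises(KeyError, match="pair"):
            stats.delta_profile(self._profiles(), {"ad1": "HC99"})


class TestSpearmanLayers:
    def test_perfect_monotone(self):
        rho, _ = stats.spearman_layers([1, 2, 3, 4, 5, 6], [2, 4, 8, 9, 12, 20])
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        rho, _ = stats.spearman_layers([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_for_perfect_correlation_n6(self):
        _, p = stats.spearman_layers(np.arange(6.0), np.arange(6.0) * 2)
        assert p == pytest.approx(2 / 720)

    def test_exact_p_matches_scipy_permutation_test(self):
        rng = np.random.default_rng(14)
        for _ in range(15):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rho, p = stats.spearman_layers(x, y)

            def statistic(perm_y):
                return sps.spearmanr(x, perm_y).statistic

            ref = sps.permutation_test(
                (y,), statistic, permutation_type="pairings",
                alternative="two-sided", n_resamples=np.inf,
            )
            assert rho == pytest.approx(sps.spearmanr(x, y).statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=20), rng.normal(size=20)
        rho, p = stats.spearman_layers(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_layers_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            stats.spearman_layers([1, 2], [3, 4])
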