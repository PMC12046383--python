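"""Laminar group statistics: residualized t-tests, FDR, mixed models,
matched-pair deltas, and layer-profile correlations.

The battery applied to (subject x ROI x layer) metric profiles:

* nuisance covariates (age, sex, cortical thickness, post-mortem
  interval, fixation time) are regressed out by pooled OLS and the
  residuals compared between amyloid-negative and amyloid-positive
  subjects with a two-sample t-test, per (ROI, layer) cell and per layer
  pooled over ROIs;
* p-values are corrected with the Benjamini-Hochberg step-up across the
  ROI x layer family (28 x 6 = 168 tests in the default parcellation);
* a linear mixed model ``value ~ age + sex + braak + amyloid`` with a
  per-subject random intercept relates metrics to pathology staging;
* case-minus-matched-control laminar differences (e.g. dMD) are
  correlated with stain density profiles across the six layers by
  Spearman rank correlation, with an exact permutation p-value at the
  tiny n involved.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "residualize",
    "group_ttest",
    "fdr_bh",
    "fit_stage_lmm",
    "delta_profile",
    "spearman_layers",
]

#: nuisance covariates regressed out before group comparison
DEFAULT_COVARIATES = ("age", "sex", "thickness_mm", "pmi_min", "ft_days")

_LAYER_ORDER = ("I", "II", "III", "IV", "V", "VI")


def _covariate_design(cohort: pd.DataFrame, covariates) -> np.ndarray:
    """Numeric design matrix [1, covariates...] with sex coded 0/1."""
    cols = [np.ones(len(cohort))]
    kept = ["intercept"]
    for c in covariates:
        v = cohort[c]
        if v.dtype == object or str(v.dtype) == "category":
            v = (v.astype(str) == "M").astype(float)  # sex: M=1, F=0
        v = np.asarray(v, dtype=float)
        if np.ptp(v) == 0:
            logger.info("covariate %r is constant; dropped from the design", c)
            continue
        cols.append(v)
        kept.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an offending column by leave-one-out rank
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"collinear covariate: {kept[j]!r}")
        raise ValueError("collinear covariate design")
    return X


def residualize(
    values: np.ndarray, cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> np.ndarray:
    """Residuals of a pooled OLS of values on nuisance covariates.

    The regression pools all subjects and deliberately excludes group
    membership, so group differences survive in the residuals while
    covariate-driven variance is removed.  Residuals have mean zero.
    """
    y = np.asarray(values, dtype=float)
    if len(y) != len(cohort):
        raise ValueError("values and cohort table length mismatch")
    X = _covariate_design(cohort, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"need more subjects ({len(y)}) than design columns ({X.shape[1]})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool = False):
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def group_ttest(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str = "MD",
    covariates=DEFAULT_COVARIATES,
    welch: bool = False,
    residualize_values: bool = True,
) -> pd.DataFrame:
    """Two-sample t-tests of amyloid-negative vs amyloid-positive subjects.

    Performed on covariate-residualized values at two granularities: per
    (ROI, layer) cell, and per layer pooled over ROIs (subject values
    averaged across ROIs first).  The sign convention lists the
    amyloid-negative group first, so a *negative* t means the
    amyloid-positive group has the higher values.

    Returns a StatResult table (layer, roi, metric, t, p, n_neg, n_pos,
    model); BH q-values are added separately by :func:`fdr_bh`.
    """
    df = profiles[profiles["metric"] == metric].copy()
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    cov = cohort.set_index("subject")

    def run_cell(sub: pd.DataFrame, roi_label):
        wide = sub.set_index("subject")["value"]
        subjects = [s for s in cov.index if s in wide.index]
        y = wide.loc[subjects].to_numpy(dtype=float)
        tab = cov.loc[subjects]
        if residualize_values:
            y = residualize(y, tab.reset_index(), covariates)
        neg = y[(tab["ab_status"] == "negative").to_numpy()]
        pos = y[(tab["ab_status"] == "positive").to_numpy()]
        if len(neg) < 2 or len(pos) < 2:
            logger.info("cell %s skipped: group with < 2 subjects", roi_label)
            return None
        t, p = _pooled_t(neg, pos, welch=welch)
        return {
            "layer": sub["layer"].iloc[0], "roi": roi_label, "metric": metric,
            "t": t, "p": p, "n_neg": len(neg), "n_pos": len(pos),
            "model": "welch_t" if welch else "student_t",
        }

    rows = []
    for (roi, layer), sub in df.groupby(["roi", "layer"], sort=True):
        r = run_cell(sub, roi)
        if r is not None:
            rows.append(r)
    # pooled per layer: average each subject over ROIs first
    pooled = (
        df.groupby(["subject", "layer"], as_index=False)["value"].mean()
        .assign(metric=metric)
    )
    for layer, sub in pooled.groupby("layer", sort=True):
        r = run_cell(sub, "pooled")
        if r is not None:
            rows.append(r)
    columns = ["layer", "roi", "metric", "t", "p", "n_neg", "n_pos", "model"]
    if not rows:
        logger.warning("no testable cells (a group has < 2 subjects everywhere)")
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["layer"] = pd.Categorical(out["layer"], categories=_LAYER_ORDER, ordered=True)
    return out.sort_values(["roi", "layer"], key=lambda s: s.astype(str)).reset_index(
        drop=True
    )


def fdr_bh(pvals, alpha: float = 0.05):
    """Benjamini-Hochberg step-up q-values and rejection flags.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, mapped back to the
    input order; a test is significant when its q <= alpha (equivalent
    to the largest-i step-up rule).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and within [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0, 1)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def fit_stage_lmm(
    profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    metric: str = "MD",
    per_layer: bool = True,
) -> pd.DataFrame:
    """Linear mixed model of a metric against pathology staging.

    Fixed effects [intercept, age, sex, Braak stage, Amyloid stage] with
    a random intercept per subject, fit by REML.  With ``per_layer`` the
    model pools a layer's cells across ROIs (several observations per
    subject, random intercept estimable); otherwise one fit per
    (ROI, layer) cell, where a single observation per subject makes the
    random intercept inestimable and the fit degrades to OLS with a
    ``model = "ols_fallback"`` flag.

    Returns one row per (scope, coefficient): (roi, layer, metric, term,
    coef, t, p, model).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = profiles[profiles["metric"] == metric].merge(
        cohort, on="subject", validate="many_to_one"
    )
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    df = df.assign(sex01=(df["sex"].astype(str) == "M").astype(float))

    terms = ["age", "sex01", "braak", "amyloid"]
    for t in terms:
        if np.ptp(df[t].to_numpy(dtype=float)) == 0:
            raise ValueError(f"staging/covariate column {t!r} is constant")

    def fit_one(sub: pd.DataFrame, roi_label, layer_label):
        rows = []
        multi_obs = sub.groupby("subject").size().max() > 1
        if multi_obs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "value ~ age + sex01 + braak + amyloid",
                    data=sub, groups=sub["subject"],
                )
                try:
                    fit = model.fit(reml=True)
                    tag = "lmm_reml"
                    params, tvals, pvals = fit.params, fit.tvalues, fit.pvalues
                except Exception:  # singular covariance etc.
                    multi_obs = False
        if not multi_obs:
            X = sm.add_constant(sub[terms].astype(float))
            fit = sm.OLS(sub["value"].astype(float), X).fit()
            tag = "ols_fallback"
            params, tvals, pvals = fit.params, fit.tvalues, fit.pvalues
        rename = {"Intercept": "intercept", "const": "intercept", "sex01": "sex"}
        for term in params.index:
            if term == "Group Var":
                continue
            rows.append(
                {
                    "roi": roi_label, "layer": layer_label, "metric": metric,
                    "term": rename.get(term, term),
                    "coef": float(params[term]),
                    "t": float(tvals[term]), "p": float(pvals[term]),
                    "model": tag,
                }
            )
        return rows

    out = []
    if per_layer:
        for layer, sub in df.groupby("layer", sort=True):
            out += fit_one(sub, "pooled", layer)
    else:
        for (roi, layer), sub in df.groupby(["roi", "layer"], sort=True):
            out += fit_one(sub, roi, layer)
    return pd.DataFrame(out)


def delta_profile(
    profiles: pd.DataFrame, pairs: dict, metric: str = "MD"
) -> pd.DataFrame:
    """Case-minus-matched-control laminar differences (e.g. dMD).

    ``pairs`` maps each case subject id to its matched control id (the
    matching is declared explicitly, as in age/sex hand-matching).
    Returns rows (case, matched_hc, roi, layer, metric, delta); a cell
    missing on either side is logged and omitted.
    """
    df = profiles[profiles["metric"] == metric]
    rows = []
    for case, hc in pairs.items():
        c = df[df["subject"] == case].set_index(["roi", "layer"])["value"]
        h = df[df["subject"] == hc].set_index(["roi", "layer"])["value"]
        if c.empty or h.empty:
            raise KeyError(f"no {metric} profile for pair ({case!r}, {hc!r})")
        common = c.index.intersection(h.index)
        missing = c.index.symmetric_difference(h.index)
        if len(missing):
            logger.info("pair (%s, %s): %d unmatched cells", case, hc, len(missing))
        for roi, layer in common:
            rows.append(
                {
                    "case": case, "matched_hc": hc, "roi": roi, "layer": layer,
                    "metric": metric, "delta": float(c.loc[(roi, layer)] - h.loc[(roi, layer)]),
                }
            )
    return pd.DataFrame(rows)


def _spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    ra = sps.rankdata(a)  # average ranks for ties
    rb = sps.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        raise ValueError("constant sequence: Spearman rho undefined")
    return float((ra * rb).sum() / denom)


def spearman_layers(x, y, exact_max_n: int = 8):
    """Spearman rank correlation across layers with a small-n exact p.

    For n <= ``exact_max_n`` the two-sided p-value is computed by full
    enumeration of the n! orderings of one sequence (the null of
    exchangeable ranks); beyond that the asymptotic t approximation is
    used.  Returns ``(rho, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired layers")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        ry = sps.rankdata(y)
        tol = 1e-12
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x, ry[list(perm)])
            if abs(r) >= abs(rho) - tol:
                count += 1
        p = count / total
    else:
        # t approximation with n-2 dof
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return rho, float(p)
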