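"""Condition and group contrasts on envelopes and latencies.

Covers the statistical layer downstream of envelope extraction and latency
mapping: cluster-corrected permutation tests on trial-mean envelopes, a
linear mixed model of median band power with uncertainty x group fixed
effects and subjects nested in ROIs as random intercepts, the
caudo-rostral gradient regression on normalised latencies, Wilcoxon
rank-sum group comparisons, and the Fisher-exact / odds-ratio contingency
analysis of demographics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ClusterTestResult", "GradientFit", "PowerLMMResult",
    "cluster_permutation_test", "fit_power_lmm", "latency_gradient",
    "compare_group_latencies", "contingency_odds_ratio", "mixed_anova",
]


# ---------------------------------------------------------------------------
# cluster-corrected permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTestResult:
    """Suprathreshold clusters of a paired-samples t map."""

    clusters: list          # (t_start, t_end, mass) in seconds
    p_values: list
    t_map: np.ndarray
    times: np.ndarray
    threshold: float
    n_perm: int


def _clusters_from_map(tmap, thr):
    """Contiguous runs where t exceeds +thr or falls below -thr, with
    (start, end, mass) in sample indices."""
    out = []
    for sign in (1, -1):
        mask = sign * tmap > thr
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(
            np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((int(s), int(e), float(tmap[s:e].sum())))
    return out


def _paired_t_maps(diffs):
    """t map(s) over the last axis of subject x time (or perm x subject x
    time) difference arrays, along the subject axis."""
    n = diffs.shape[-2]
    mean = diffs.mean(axis=-2)
    sd = diffs.std(axis=-2, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def cluster_permutation_test(env_a, env_b, times, window=(0.1, 1.0),
                             n_perm: int = 10_000, seed: int = 0,
                             cluster_alpha: float = 0.05
                             ) -> ClusterTestResult:
    """Paired cluster-corrected permutation test between two conditions.

    Parameters
    ----------
    env_a, env_b : array, subject x time
        Trial-mean envelopes per subject for the two conditions (paired).
    times : array
        Time axis in seconds; the test is restricted to ``window``.
    n_perm : int
        Sign-flip permutations for the max-cluster-mass null.
    cluster_alpha : float
        Two-tailed cluster-forming threshold on the paired t map.

    Returns
    -------
    ClusterTestResult with cluster extents in seconds and permutation
    p-values (proportion of permuted max |mass| >= observed |mass|).
    """
    a = np.asarray(env_a, dtype=float)
    b = np.asarray(env_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must be paired (same shape)")
    n_sub = a.shape[0]
    if n_sub < 6:
        raise ValueError("need >= 6 subjects for a usable sign-flip null")
    times = np.asarray(times, dtype=float)
    sel = (times >= window[0]) & (times <= window[1])
    t_sel = times[sel]
    diff = (a - b)[:, sel]

    thr = stats.t.ppf(1 - cluster_alpha / 2, df=n_sub - 1)
    tmap = _paired_t_maps(diff)
    clusters = _clusters_from_map(tmap, thr)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null_max = np.zeros(n_perm)
    # vectorised permuted t maps: squares are flip-invariant
    sq_sum = np.sum(diff ** 2, axis=0)
    for i in range(n_perm):
        mean_p = flips[i] @ diff / n_sub
        var_p = (sq_sum - n_sub * mean_p ** 2) / (n_sub - 1)
        var_p = np.where(var_p <= 0, np.inf, var_p)
        tmap_p = mean_p / np.sqrt(var_p / n_sub)
        cl = _clusters_from_map(tmap_p, thr)
        null_max[i] = max((abs(m) for *_, m in cl), default=0.0)

    pvals = [(1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1)
             for *_, mass in clusters]
    clusters_sec = [(float(t_sel[s]), float(t_sel[e - 1]), mass)
                    for s, e, mass in clusters]
    return ClusterTestResult(clusters=clusters_sec, p_values=pvals,
                             t_map=tmap, times=t_sel, threshold=float(thr),
                             n_perm=n_perm)


# ---------------------------------------------------------------------------
# linear mixed model of power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerLMMResult:
    """Fixed effects and variance components of the power mixed model."""

    coefficients: pd.DataFrame   # estimate, ci_low, ci_high, p per term
    random_variances: dict
    resid_variance: float
    conditional_r2: float
    marginal_r2: float
    model: object

    def interaction_contrast(self, term: str = "au_high:group_patient"):
        """The group difference in the low-high condition effect (the
        moderation contrast) with its standard error."""
        row = self.coefficients.loc[term]
        return float(row["estimate"]), float(
            (row["ci_high"] - row["ci_low"]) / (2 * 1.96))


def fit_power_lmm(table: pd.DataFrame) -> PowerLMMResult:
    """Mixed model of median band power.

    ``table`` needs columns subject, roi, pu, au, group, power (one row per
    subject x ROI x condition cell). Fixed effects: PU, AU, Group and the
    two Group interactions, treatment-coded with low / control as the
    reference; random intercepts for ROI and for subjects nested within
    ROI. Estimated by maximum likelihood.
    """
    df = table.copy()
    if df["roi"].nunique() < 2 or df["subject"].nunique() < 4:
        raise ValueError("need >= 2 ROIs and >= 4 subjects")
    df["pu_high"] = (df["pu"] == "high").astype(float)
    df["au_high"] = (df["au"] == "high").astype(float)
    df["group_patient"] = (df["group"] == "patient").astype(float)

    model = smf.mixedlm(
        "power ~ pu_high + au_high + group_patient + pu_high:group_patient"
        " + au_high:group_patient",
        df, groups=df["roi"], re_formula="1",
        vc_formula={"subject": "0 + C(subject)"})
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)

    terms = [t for t in fit.params.index if t != "Group Var"
             and not t.endswith(" Var")]
    ci = fit.conf_int()
    coefs = pd.DataFrame({
        "estimate": fit.params[terms],
        "ci_low": ci.loc[terms, 0],
        "ci_high": ci.loc[terms, 1],
        "p": fit.pvalues[terms],
    })
    re_var = {"roi": float(fit.cov_re.iloc[0, 0])}
    if fit.vcomp.size:
        re_var["subject_in_roi"] = float(fit.vcomp[0])
    resid = float(fit.scale)
    fe_pred = np.asarray(model.exog @ fit.fe_params)
    var_f = float(np.var(fe_pred))
    var_r = sum(re_var.values())
    cond_r2 = (var_f + var_r) / (var_f + var_r + resid)
    marg_r2 = var_f / (var_f + var_r + resid)
    return PowerLMMResult(coefficients=coefs, random_variances=re_var,
                          resid_variance=resid, conditional_r2=cond_r2,
                          marginal_r2=marg_r2, model=fit)


# ---------------------------------------------------------------------------
# latency gradient along the dorsal path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientFit:
    """OLS fit of normalised latency on caudo-rostral position."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    bootstrap_ci: tuple


def latency_gradient(latencies: pd.DataFrame, positions: dict,
                     n_boot: int = 2000, seed: int = 0) -> GradientFit:
    """Regression of mean normalised latency on caudo-rostral position.

    Parameters
    ----------
    latencies : DataFrame
        Columns roi, norm_latency and optionally subject. With a subject
        column the ROI means are regressed and the slope CI is
        bootstrapped over subjects; without it, the rows are taken as ROI
        means and the CI falls back to the OLS interval.
    positions : dict roi -> caudo-rostral coordinate
        Only ROIs present here enter the fit (the dorsal-path subset).
    """
    df = latencies[latencies["roi"].isin(positions)].copy()
    rois = sorted(df["roi"].unique())
    if len(rois) < 4:
        raise ValueError("need >= 4 dorsal-path ROIs with latencies")
    pos = np.array([positions[r] for r in rois], dtype=float)

    def roi_means(frame):
        return frame.groupby("roi")["norm_latency"].mean().reindex(
            rois).to_numpy()

    y = roi_means(df)
    X = sm.add_constant(pos)
    ols = sm.OLS(y, X).fit()
    slope, intercept = float(ols.params[1]), float(ols.params[0])

    if "subject" in df.columns and df["subject"].nunique() > 1:
        rng = np.random.default_rng(seed)
        subjects = df["subject"].unique()
        groups = {s: g for s, g in df.groupby("subject")}
        boot = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.choice(subjects, size=subjects.size, replace=True)
            resampled = pd.concat([groups[s] for s in pick])
            yb = roi_means(resampled)
            ok = np.isfinite(yb)
            if ok.sum() < 3:
                boot[i] = np.nan
                continue
            boot[i] = np.polyfit(pos[ok], yb[ok], 1)[0]
        lo, hi = np.nanpercentile(boot, [2.5, 97.5])
        ci = (float(min(lo, slope)), float(max(hi, slope)))
    else:
        lo, hi = ols.conf_int()[1]
        ci = (float(lo), float(hi))
    return GradientFit(slope=slope, intercept=intercept,
                       r_squared=float(ols.rsquared),
                       p_value=float(ols.pvalues[1]), bootstrap_ci=ci)


# ---------------------------------------------------------------------------
# rank and contingency tests
# ---------------------------------------------------------------------------

def compare_group_latencies(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum comparison of two independent samples.

    Returns ``(W, p)`` where W is the rank sum of the first sample
    (midrank convention); exact p for small tie-free samples, normal
    approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    w = float(res.statistic + a.size * (a.size + 1) / 2)
    return w, float(res.pvalue)


def contingency_odds_ratio(table):
    """Sample odds ratio and Fisher exact p for a 2x2 count table.

    Rows are groups, columns outcomes; for ``[[a, b], [c, d]]`` the odds
    ratio is ``a*d / (b*c)`` — the odds of the first column in the first
    row relative to the second row. A zero off-diagonal margin leaves the
    ratio undefined (nan).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(
            t.dtype, np.integer):
        raise ValueError("need a 2x2 table of non-negative integers")
    (a, b), (c, d) = t
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str) -> pd.DataFrame:
    """Thin convenience wrapper for mixed-design repeated-measures ANOVA."""
    import pingouin as pg
    return pg.mixed_anova(data=data, dv=dv, within=within,
                          between=between, subject=subject)
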