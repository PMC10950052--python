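"""Group statistics: cluster permutation tests, the power mixed model,
gradient regression, rank and contingency tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import hypergeom, rankdata

from lbacascade.group_stats import (cluster_permutation_test,
                                    compare_group_latencies,
                                    contingency_odds_ratio, fit_power_lmm,
                                    latency_gradient)

TIMES = np.arange(-0.5, 1.5, 0.01)


def test_injected_offset_is_localised():
    """A sustained -2% offset over 0.3-0.7 s is detected by a cluster
    overlapping most of the injected window."""
    rng = np.random.default_rng(0)
    n = 20
    a = rng.normal(0, 1, (n, TIMES.size))
    b = a + rng.normal(0, 1, (n, TIMES.size))
    inj = (TIMES >= 0.3) & (TIMES <= 0.7)
    a[:, inj] -= 2.0
    res = cluster_permutation_test(a, b, TIMES, n_perm=500, seed=1)
    sig = [(c, p) for c, p in zip(res.clusters, res.p_values) if p < 0.05]
    assert sig
    (t0, t1, mass), p = max(sig, key=lambda cp: abs(cp[0][2]))
    assert mass < 0
    overlap = max(0.0, min(t1, 0.7) - max(t0, 0.3))
    assert overlap >= 0.8 * 0.4


def test_label_swap_flips_cluster_sign():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, (12, TIMES.size))
    b = rng.normal(0.5, 1, (12, TIMES.size))
    r1 = cluster_permutation_test(a, b, TIMES, n_perm=300, seed=3)
    r2 = cluster_permutation_test(b, a, TIMES, n_perm=300, seed=3)
    m1 = sorted(round(c[2], 6) for c in r1.clusters)
    m2 = sorted(round(-c[2], 6) for c in r2.clusters)
    assert m1 == m2
    assert sorted(np.round(r1.p_values, 6)) == sorted(
        np.round(r2.p_values, 6))


def test_cluster_test_needs_enough_subjects():
    with pytest.raises(ValueError, match="6 subjects"):
        cluster_permutation_test(np.zeros((4, 200)), np.zeros((4, 200)),
                                 TIMES)


def _lmm_table(beta, seed, n_per_group=19, n_roi=12, sd_roi=1.0,
               sd_subj=1.0):
    """Simulate from the power mixed model: ROI intercepts plus subject
    intercepts nested within ROI plus unit residual noise."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["control"] * n_per_group + ["patient"] * n_per_group
    rois = [f"r{k}" for k in range(n_roi)]
    u_roi = {r: rng.normal(0, sd_roi) for r in rois}
    for g_i, grp in enumerate(groups):
        sid = f"s{g_i}"
        for roi in rois:
            u_sr = rng.normal(0, sd_subj)
            for pu in ("low", "high"):
                for au in ("low", "high"):
                    y = (beta[0] + u_roi[roi] + u_sr
                         + beta[1] * (pu == "high")
                         + beta[2] * (au == "high")
                         + beta[3] * (grp == "patient")
                         + beta[4] * (pu == "high") * (grp == "patient")
                         + beta[5] * (au == "high") * (grp == "patient")
                         + rng.normal())
                    rows.append(dict(subject=sid, roi=roi, pu=pu, au=au,
                                     group=grp, power=y))
    return pd.DataFrame(rows)


def test_lmm_recovers_generating_effects_within_ci():
    """Each fixed effect lies inside its 95% CI in >= 90% of simulated
    cohorts generated at the reference effect sizes."""
    beta = (0.0, 1.3, -2.73, 0.5, 0.0, 0.42)
    terms = ["Intercept", "pu_high", "au_high", "group_patient",
             "pu_high:group_patient", "au_high:group_patient"]
    hits = np.zeros(6)
    n_seeds = 50
    for seed in range(n_seeds):
        res = fit_power_lmm(_lmm_table(beta, seed=seed))
        for j, term in enumerate(terms):
            row = res.coefficients.loc[term]
            hits[j] += row["ci_low"] <= beta[j] <= row["ci_high"]
    assert np.all(hits >= 0.9 * n_seeds)


def test_lmm_interaction_contrast_sign():
    beta = (0.0, 1.3, -2.73, 0.5, 0.0, 0.42)
    agree = 0
    n_seeds = 20
    for seed in range(n_seeds):
        res = fit_power_lmm(_lmm_table(beta, seed=200 + seed))
        est, _ = res.interaction_contrast("au_high:group_patient")
        agree += est > 0
    assert agree >= 0.95 * n_seeds - 1


def test_lmm_balanced_fixed_effects_match_ols():
    df = _lmm_table((0.0, 1.0, -2.0, 0.5, 0.2, 0.3), seed=7)
    res = fit_power_lmm(df)
    X = pd.DataFrame({
        "pu_high": (df["pu"] == "high").astype(float),
        "au_high": (df["au"] == "high").astype(float),
        "group_patient": (df["group"] == "patient").astype(float),
    })
    X["pu_high:group_patient"] = X["pu_high"] * X["group_patient"]
    X["au_high:group_patient"] = X["au_high"] * X["group_patient"]
    ols = sm.OLS(df["power"], sm.add_constant(X)).fit()
    for term in ["pu_high", "au_high", "pu_high:group_patient",
                 "au_high:group_patient"]:
        assert res.coefficients.loc[term, "estimate"] == pytest.approx(
            ols.params[term], abs=1e-5)


def test_lmm_degenerate_nesting_r2():
    """With no random-effect variance the conditional and marginal R2
    coincide."""
    df = _lmm_table((0.0, 1.0, -2.0, 0.0, 0.0, 0.0), seed=8,
                    sd_roi=0.0, sd_subj=0.0)
    res = fit_power_lmm(df)
    assert res.conditional_r2 == pytest.approx(res.marginal_r2, abs=0.02)


def test_gradient_exact_line_and_constant():
    lat = pd.DataFrame({"roi": [f"d{i}" for i in range(8)],
                        "norm_latency": 0.2 + 0.05 * np.arange(8)})
    pos = {f"d{i}": float(i) for i in range(8)}
    gf = latency_gradient(lat, pos)
    assert gf.slope == pytest.approx(0.05, abs=1e-12)
    assert gf.r_squared == pytest.approx(1.0)
    flat = lat.assign(norm_latency=0.3)
    gf0 = latency_gradient(flat, pos)
    assert gf0.slope == pytest.approx(0.0, abs=1e-12)


def test_gradient_needs_enough_rois():
    lat = pd.DataFrame({"roi": ["a", "b", "c"],
                        "norm_latency": [0.1, 0.2, 0.3]})
    with pytest.raises(ValueError, match="4"):
        latency_gradient(lat, {"a": 0.0, "b": 1.0, "c": 2.0})


def test_gradient_bootstrap_ci_covers_true_slope():
    """Bootstrap-over-subjects CI covers the generating slope in roughly
    95% of replications."""
    true_slope = 0.02
    pos = {f"d{i}": float(i) for i in range(8)}
    cover = 0
    n_rep = 100
    for rep in range(n_rep):
        rng = np.random.default_rng(rep)
        rows = []
        for s in range(12):
            offs = rng.normal(0, 0.05)
            for i in range(8):
                rows.append(dict(subject=f"s{s}", roi=f"d{i}",
                                 norm_latency=0.2 + true_slope * i + offs
                                 + rng.normal(0, 0.03)))
        gf = latency_gradient(pd.DataFrame(rows), pos, n_boot=300,
                              seed=rep)
        cover += gf.bootstrap_ci[0] <= true_slope <= gf.bootstrap_ci[1]
    assert 0.88 * n_rep <= cover <= n_rep


def test_wilcoxon_matches_manual_ranks():
    a, b = [1.2, 0.7, 3.1, 2.2, 0.4], [1.9, 2.8, 3.3, 0.9, 2.5]
    w, p = compare_group_latencies(a, b)
    ranks = rankdata(np.concatenate([a, b]))
    assert w == pytest.approx(ranks[:5].sum())
    assert 0 < p <= 1


def test_wilcoxon_detects_large_shift_and_identity():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 20)
    b = rng.normal(5, 1, 20)
    _, p = compare_group_latencies(a, b)
    assert p < 0.001
    x = [1, 2, 3, 4, 5]
    _, p_same = compare_group_latencies(x, x)
    assert p_same == pytest.approx(1.0, abs=1e-9)


def test_odds_ratio_identity_table():
    odds, p = contingency_odds_ratio([[5, 5], [5, 5]])
    assert odds == 1.0
    assert p == pytest.approx(1.0)


def test_fisher_p_matches_hypergeometric_enumeration():
    table = [[7, 3], [2, 8]]
    _, p = contingency_odds_ratio(table)
    # enumerate all tables with the same margins
    a_obs = 7
    n1, n2, m1 = 10, 10, 9
    probs = {a: hypergeom.pmf(a, n1 + n2, m1, n1)
             for a in range(max(0, m1 - n2), min(n1, m1) + 1)}
    p_manual = sum(pr for pr in probs.values()
                   if pr <= probs[a_obs] * (1 + 1e-9))
    assert p == pytest.approx(p_manual, rel=1e-6)


def test_odds_ratio_zero_margin_flagged():
    odds, _ = contingency_odds_ratio([[5, 0], [5, 5]])
    assert np.isnan(odds)
    with pytest.raises(ValueError):
        contingency_odds_ratio([[1.5, 2], [3, 4]])
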