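"""Latency mapping: predicted trajectories, lagged rank correlation,
sign test, surrogates, FDR."""

import numpy as np
import pytest
from scipy.stats import kstest

from lbacascade.lba import (LBAParameters, cell_index, make_design,
                            simulate_lba, trials_to_dataframe)
from lbacascade.latency import (_trajectory_values, fdr_correct,
                                max_lagged_spearman, phase_randomize,
                                predict_activity, roi_sign_test)


# ---------------------------------------------------------------------------
# predicted trajectories
# ---------------------------------------------------------------------------

def _one_option_trial(rt=0.9):
    return {"pu": "low", "au": "low", "rt": rt, "n_options": 1}


def test_single_option_ramp_geometry():
    """With a vanishing start-point range the trajectory ramps from ~0 at
    tau1 with the rescaled slope, reaching the bound at rt - tau2."""
    p = LBAParameters(v=2.0, b=1.2, z=1e-9, t0=0.3, s=1.0)
    rt, tau1 = 0.9, 0.12
    traj = predict_activity(_one_option_trial(rt), p, tau1, fs=100.0)
    assert traj.tau2 == pytest.approx(0.3 - tau1)
    before = traj.values[traj.times < tau1]
    assert np.allclose(before, 0.0, atol=1e-8)
    # bound reached exactly at the end of accumulation
    i_end = np.searchsorted(traj.times, rt - traj.tau2)
    assert traj.values[i_end] == pytest.approx(1.2, abs=0.03)
    after = traj.values[traj.times > rt - traj.tau2 + 0.01]
    assert np.allclose(after, after[0] if after.size else 1.2, atol=1e-8)


def test_tau1_zero_boundary_split():
    p = LBAParameters(v=2.0, b=1.2, z=0.4, t0=0.3, s=1.0)
    traj = predict_activity(_one_option_trial(), p, 0.0)
    assert traj.tau2 == pytest.approx(0.3)
    # accumulation starts immediately: no flat pre-segment beyond t=0
    assert traj.values[1] > traj.values[0]


def test_three_option_sum_dominates_single():
    p = LBAParameters(v=2.0, b=1.2, z=0.4, t0=0.3, s=1.0)
    t1 = predict_activity(_one_option_trial(), p, 0.1)
    t3 = predict_activity({"pu": "low", "au": "low", "rt": 0.9,
                           "n_options": 3}, p, 0.1)
    i = np.searchsorted(t3.times, 0.9 - t3.tau2)
    assert t3.values[i] >= t1.values[i]


def test_tau1_outside_nondecision_time_rejected():
    p = LBAParameters(v=2.0, b=1.2, z=0.4, t0=0.3, s=1.0)
    with pytest.raises(ValueError, match="tau1"):
        predict_activity(_one_option_trial(), p, 0.35)
    with pytest.raises(ValueError, match="rt"):
        predict_activity(_one_option_trial(rt=0.2), p, 0.1)


# ---------------------------------------------------------------------------
# lagged correlation
# ---------------------------------------------------------------------------

def _embedded_envelopes(params, df, true_tau, fs=100.0, noise=0.01,
                        seed=0):
    """Envelope epochs that are exact negatives of the predicted
    trajectories at the given accumulation-onset latency."""
    rng = np.random.default_rng(seed)
    times = -0.5 + np.arange(200) / fs
    onset = times >= 0
    env = np.zeros((len(df), 200))
    for i in range(len(df)):
        rt = df.rt[i]
        ci = cell_index(df.pu[i], df.au[i])
        v, b, z, t0 = params.cell(ci)
        if rt <= t0 + 0.02:
            continue
        m = len(df.options[i].split("|"))
        traj = _trajectory_values(np.minimum(times[onset], rt), rt,
                                  v, b, z, t0, m, min(true_tau, t0 - 0.01))
        env[i, onset] = -traj
    return env + noise * rng.standard_normal(env.shape)


@pytest.fixture(scope="module")
def embedded(cell_params):
    df = trials_to_dataframe(
        simulate_lba(cell_params, make_design(40, seed=0), seed=2))
    env = _embedded_envelopes(cell_params, df, true_tau=0.12)
    return df, env


def test_embedded_signal_recovery(cell_params, embedded):
    df, env = embedded
    rho, tau1, tau2 = max_lagged_spearman(env, df, cell_params)
    assert rho < -0.9
    assert abs(tau1 - 0.12) <= 0.01  # within one lag step
    assert tau1 + tau2 == pytest.approx(0.35, abs=1e-9)


def test_rank_invariance_to_monotone_transform(cell_params, embedded):
    df, env = embedded
    rho_a, tau_a, _ = max_lagged_spearman(env, df, cell_params)
    warped = np.exp(env / np.abs(env).max())  # strictly increasing
    rho_b, tau_b, _ = max_lagged_spearman(warped, df, cell_params)
    assert abs(rho_b) == pytest.approx(abs(rho_a), abs=1e-12)
    assert tau_b == tau_a


def test_white_noise_envelopes_give_small_correlations(cell_params):
    p = LBAParameters(v=3.0, b=1.2, z=0.6, t0=0.35, s=1.0)
    df = trials_to_dataframe(
        simulate_lba(p, make_design(3, seed=3), seed=4))
    abs_rhos = []
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        env = rng.standard_normal((len(df), 200))
        rho, _, _ = max_lagged_spearman(env, df, p)
        abs_rhos.append(abs(rho))
    assert np.mean(abs_rhos) < 0.1


def test_too_few_samples_rejected():
    p = LBAParameters(v=3.0, b=1.2, z=0.6, t0=0.1, s=1.0)
    df = trials_to_dataframe(
        simulate_lba(p, [("low", "low", frozenset({0}))], seed=5))
    df.loc[0, "rt"] = 0.25  # 26 concatenated samples only
    with pytest.raises(ValueError, match="30"):
        max_lagged_spearman(np.zeros((1, 200)), df, p)


# ---------------------------------------------------------------------------
# sign test
# ---------------------------------------------------------------------------

def test_sign_test_all_negative_matches_exact_binomial():
    z, p, dropped = roi_sign_test(-np.abs(np.random.default_rng(0)
                                          .normal(size=21)) - 0.01)
    exact = 2 * 0.5 ** 21
    assert dropped == 0
    assert z < 0
    assert p == pytest.approx(exact, rel=0.1)


def test_sign_test_balance_gives_zero_z():
    vals = np.concatenate([np.ones(10), -np.ones(10)])
    z, p, _ = roi_sign_test(vals)
    assert z == 0.0
    assert p == pytest.approx(1.0)


def test_sign_test_flip_symmetry():
    rng = np.random.default_rng(1)
    vals = rng.normal(0.3, 1.0, size=15)
    z1, p1, _ = roi_sign_test(vals)
    z2, p2, _ = roi_sign_test(-vals)
    assert z2 == -z1
    assert p2 == p1


def test_sign_test_drops_exact_zeros():
    vals = np.array([0.0, 0.0, 1, 1, 1, -1, 2, 3])
    z, p, dropped = roi_sign_test(vals)
    assert dropped == 2


# ---------------------------------------------------------------------------
# surrogates and FDR
# ---------------------------------------------------------------------------

def test_phase_randomization_preserves_amplitude_spectrum():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(256)
    surr = phase_randomize(x, seed=0)
    assert np.allclose(np.abs(np.fft.rfft(surr)),
                       np.abs(np.fft.rfft(x)), atol=1e-10)
    assert surr.mean() == pytest.approx(x.mean(), abs=1e-12)
    assert not np.allclose(surr, x)


def test_phase_randomization_preserves_autocorrelation():
    """Equal amplitude spectra imply equal autocorrelation functions
    (Wiener-Khinchin)."""
    rng = np.random.default_rng(3)
    x = np.convolve(rng.standard_normal(600), np.ones(10) / 10,
                    mode="valid")
    surr = phase_randomize(x, seed=1)

    def circular_acf(y):
        f = np.fft.fft(y - y.mean())
        return np.real(np.fft.ifft(f * np.conj(f)))

    assert np.allclose(circular_acf(surr), circular_acf(x), atol=1e-8)


def test_phase_randomization_odd_length_and_short_input():
    x = np.sin(np.arange(255) * 0.1)
    surr = phase_randomize(x, seed=2)
    assert np.allclose(np.abs(np.fft.rfft(surr)),
                       np.abs(np.fft.rfft(x)), atol=1e-10)
    with pytest.raises(ValueError):
        phase_randomize(np.zeros(8))


def test_fdr_hand_computed_examples():
    qvals, rej = fdr_correct([0.001, 0.02, 0.9])
    assert qvals == pytest.approx([0.003, 0.03, 0.9])
    assert rej.tolist() == [True, True, False]
    qvals, _ = fdr_correct(np.full(10, 0.01))
    assert np.allclose(qvals, 0.01)


def test_fdr_monotone_in_sorted_pvalues():
    rng = np.random.default_rng(4)
    p = np.sort(rng.uniform(size=30))
    q, _ = fdr_correct(p)
    assert np.all(np.diff(q) >= -1e-12)


def test_null_pvalues_are_roughly_uniform_after_smoothing():
    """Permutation-style p-values built from exchangeable null draws stay
    close to uniform (sanity for the add-one-smoothing convention)."""
    rng = np.random.default_rng(5)
    pvals = []
    for _ in range(200):
        obs, null = rng.standard_normal(), rng.standard_normal(199)
        pvals.append((1 + np.sum(np.abs(null) >= abs(obs))) / 200)
    assert kstest(pvals, "uniform").pvalue > 0.05
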