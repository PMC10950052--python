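"""Localising the onset of evidence accumulation in power envelopes.

The accumulator model fixes, for every trial, the duration of evidence
accumulation (rt - t0) but not where inside the trial it starts: the
non-decision time t0 can be split into a pre-accumulation part tau1
(sensory encoding) and a post-accumulation part tau2 (motor execution),
with tau1 + tau2 = t0. For each candidate tau1 on a 10-ms grid, the model
predicts a per-trial activity trace — the summed engaged accumulators,
flat until tau1, rising linearly until the winner hits the bound at
rt - tau2, flat afterwards. Concatenating all trials of a subject and
rank-correlating the predictions with the measured ROI envelope gives a
lagged Spearman profile; the tau1 maximising |rho| is that ROI's
accumulation-onset latency. Because band power *de*synchronises while
evidence accumulates, the correlation of interest is negative.

Group-level significance per ROI combines a sign test on the
Fisher-transformed per-subject correlations with a phase-randomised
surrogate null (amplitude spectra preserved, phases scrambled) and
Benjamini-Hochberg FDR across ROIs and bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .lba import LBAParameters, cell_index, trials_to_arrays

__all__ = [
    "PredictedTrajectory", "predict_activity", "max_lagged_spearman",
    "roi_sign_test", "phase_randomize", "permutation_null_pvalues",
    "fdr_correct", "LatencyMapper",
]


@dataclass(frozen=True)
class PredictedTrajectory:
    """Model-predicted summed accumulator activity for one trial."""

    times: np.ndarray
    values: np.ndarray
    tau1: float
    tau2: float


def _trajectory_values(times, rt, v, b, z, t0, n_opts, tau1):
    """Summed engaged-accumulator activity sampled at ``times``.

    All engaged accumulators start at the expected start point z/2 and rise
    from tau1 to rt - tau2 (= tau1 + decision time). The winner's slope is
    rescaled so it reaches the bound b exactly at decision time; losers
    ramp at the cell-mean rate v and are truncated there.
    """
    decision = rt - t0
    slope = (b - z / 2.0) / decision + (n_opts - 1) * v
    return n_opts * z / 2.0 + slope * np.clip(times - tau1, 0.0, decision)


def predict_activity(trial, params: LBAParameters, tau1: float,
                     fs: float = 100.0) -> PredictedTrajectory:
    """Predicted activity for one trial at a given pre-accumulation lag.

    ``trial`` may be a TrialRecord or a mapping with keys pu, au, rt and
    options/n_options. The trajectory runs from coherence onset (t = 0) to
    the trial's rt on a 1/fs grid.
    """
    if hasattr(trial, "pu"):
        pu, au, rt = trial.pu, trial.au, trial.rt
        n_opts = len(trial.available_options)
    else:
        pu, au, rt = trial["pu"], trial["au"], trial["rt"]
        n_opts = trial.get("n_options") or len(
            str(trial["options"]).split("|"))
    ci = cell_index(pu, au)
    v, b, z, t0 = params.cell(ci)
    if rt <= t0:
        raise ValueError(f"rt={rt} does not exceed the cell t0={t0}")
    if not (0.0 <= tau1 <= t0):
        raise ValueError(f"tau1 must lie in [0, t0={t0}], got {tau1}")
    n = int(np.floor(rt * fs)) + 1
    times = np.arange(n) / fs
    vals = _trajectory_values(times, rt, v, b, z, t0, n_opts, tau1)
    return PredictedTrajectory(times=times, values=vals, tau1=tau1,
                               tau2=t0 - tau1)


# ---------------------------------------------------------------------------
# concatenated lagged rank correlation
# ---------------------------------------------------------------------------

def _segment_layout(rts, fs, onset_index, n_time):
    """Per-trial (start, length) of the [onset, rt] segment within the
    epoch array, and slice starts within the concatenated vector."""
    max_len = n_time - onset_index
    lengths = np.minimum(np.floor(rts * fs).astype(int) + 1, max_len)
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return lengths, offsets


def _concat_segments(epochs, lengths, onset_index):
    return np.concatenate([epochs[i, onset_index:onset_index + L]
                           for i, L in enumerate(lengths)])


def _centred_ranks(x):
    r = rankdata(x)
    r -= r.mean()
    n = np.linalg.norm(r)
    return r / n if n > 0 else r


class _PredictionBank:
    """Pre-ranked concatenated predictions for every tau1 on the grid.

    Predictions depend on the trials and fitted parameters only — not on
    the ROI — so one bank per subject serves all ROIs.
    """

    def __init__(self, trials, params: LBAParameters, fs: float,
                 lag_step: float, onset_index: int, n_time: int):
        rts, cells, n_opts = trials_to_arrays(trials)
        t0s = params.t0[cells]
        usable = rts > t0s + 1.5 / fs
        self.usable = usable
        self.rts = rts[usable]
        self.cells = cells[usable]
        self.n_opts = n_opts[usable]
        self.t0 = float(np.max(params.t0))
        self.lengths, self.offsets = _segment_layout(
            self.rts, fs, onset_index, n_time)
        self.onset_index = onset_index
        n_lags = int(np.floor(self.t0 / lag_step + 1e-9)) + 1
        self.taus = np.arange(n_lags) * lag_step
        pred_ranks = []
        for tau1 in self.taus:
            segs = []
            for i in range(self.rts.size):
                t = np.arange(self.lengths[i]) / fs
                ci = self.cells[i]
                tau = min(tau1, params.t0[ci])  # cell t0 may be shorter
                segs.append(_trajectory_values(
                    t, self.rts[i], params.v[ci], params.b[ci],
                    params.z[ci], params.t0[ci], self.n_opts[i], tau))
            pred_ranks.append(_centred_ranks(np.concatenate(segs)))
        #: (n_lags, L) matrix of centred unit-norm prediction ranks
        self.pred_matrix = np.asarray(pred_ranks)
        # flat column index extracting the concatenated [onset, rt]
        # segments from a (n_trials, n_time) epoch array in one take
        self.col_index = np.concatenate([
            i * n_time + onset_index + np.arange(L)
            for i, L in enumerate(self.lengths)])
        self._n_time = n_time

    def correlate(self, env_concat):
        """Signed Spearman rho against every lagged prediction."""
        return self.pred_matrix @ _centred_ranks(env_concat)

    def correlate_epochs(self, epochs_stack):
        """Lagged rho profiles for a stack of ROI epoch arrays.

        ``epochs_stack`` is (n_roi, n_trials, n_time) restricted to the
        usable trials; returns (n_roi, n_lags). Ranks are ordinal
        (double argsort) — exact for the tie-free continuous envelopes
        this path handles.
        """
        concat = epochs_stack.reshape(epochs_stack.shape[0],
                                      -1)[:, self.col_index]
        order = np.argsort(concat, axis=-1)
        r = np.empty(concat.shape)
        np.put_along_axis(
            r, order,
            np.broadcast_to(np.arange(concat.shape[-1], dtype=float),
                            concat.shape), axis=-1)
        r -= r.mean(axis=-1, keepdims=True)
        norms = np.linalg.norm(r, axis=-1, keepdims=True)
        r /= np.where(norms > 0, norms, 1.0)
        return r @ self.pred_matrix.T


def _max_abs(rhos, taus):
    """Index of max |rho| with ties broken toward smaller tau1."""
    i = int(np.argmax(np.abs(rhos)))  # argmax returns the first maximum
    return rhos[i], taus[i]


def max_lagged_spearman(envelopes, trials, params: LBAParameters,
                        fs: float = 100.0, lag_step: float = 0.01,
                        epoch_start: float = -0.5):
    """Maximum lagged Spearman correlation for one ROI of one subject.

    Parameters
    ----------
    envelopes : array, trial x time
        Baseline-normalised envelope epochs for a single ROI (time axis
        starting at ``epoch_start``).
    trials : DataFrame or TrialRecord list
        The subject's trials, aligned with the envelope trial axis.
    params : LBAParameters
        The subject's fitted accumulator parameters.

    Returns
    -------
    (rho_signed, tau1, tau2) : the signed correlation at the optimal split
    of the non-decision time, ties toward smaller tau1.
    """
    env = np.asarray(envelopes, dtype=float)
    onset_index = int(round(-epoch_start * fs))
    bank = _PredictionBank(trials, params, fs, lag_step, onset_index,
                           env.shape[1])
    env_concat = _concat_segments(env[bank.usable], bank.lengths,
                                  onset_index)
    if env_concat.size < 30:
        raise ValueError("fewer than 30 concatenated samples")
    rhos = bank.correlate(env_concat)
    rho, tau1 = _max_abs(rhos, bank.taus)
    return float(rho), float(tau1), float(bank.t0 - tau1)


# ---------------------------------------------------------------------------
# group-level inference
# ---------------------------------------------------------------------------

def roi_sign_test(values):
    """Sign test against a zero median on per-subject statistics.

    Exact ties (zeros) are dropped. Returns ``(z, p, n_dropped)`` with the
    two-tailed p from the exact binomial and a continuity-corrected normal
    Z score.
    """
    x = np.asarray(values, dtype=float)
    nz = x[x != 0]
    dropped = int(x.size - nz.size)
    n = nz.size
    if n < 5:
        raise ValueError("need at least 5 non-zero values")
    k = int(np.sum(nz > 0))
    p = binomtest(k, n, 0.5).pvalue
    d = k - n / 2.0
    cc = 0.5 * np.sign(d)
    z = (d - cc) / (np.sqrt(n) / 2.0) if d != 0 else 0.0
    return float(z), float(p), dropped


def phase_randomize(x, seed=None, rng=None):
    """Phase-randomised surrogate preserving the amplitude spectrum.

    Phases of positive frequencies are replaced by i.i.d. uniform draws;
    DC and (for even lengths) the Nyquist bin are untouched, so the output
    is real with the original mean. Operates along the last axis.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 16:
        raise ValueError("need at least 16 samples")
    if rng is None:
        rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x, axis=-1)
    n_pos = (n - 1) // 2          # bins with a free phase
    phases = rng.uniform(0, 2 * np.pi, size=x.shape[:-1] + (n_pos,))
    spec[..., 1:1 + n_pos] = np.abs(spec[..., 1:1 + n_pos]) * np.exp(
        1j * phases)
    return np.fft.irfft(spec, n=n, axis=-1)


def fdr_correct(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up. Returns ``(qvals, discoveries)``."""
    p = np.asarray(pvals, dtype=float)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _fisher_z(r):
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def _signed_max_rows(rho_mat):
    """Signed rho at the max-|rho| lag per row (first max wins ties)."""
    idx = np.argmax(np.abs(rho_mat), axis=-1)
    return np.take_along_axis(rho_mat, idx[:, None], axis=-1)[:, 0], idx


class LatencyMapper(BaseEstimator):
    """Group latency mapping over ROIs.

    ``fit`` takes per-subject envelope arrays, trial tables and fitted
    accumulator parameters, estimates the per-subject per-ROI lagged
    correlations, and assembles the group map with sign-test statistics,
    phase-randomisation permutation p-values and FDR-corrected q-values.

    Parameters
    ----------
    lag_step : float
        tau1 grid resolution in seconds (one envelope sample).
    n_perm : int
        Surrogate iterations for the permutation null (0 disables it).
    q : float
        FDR level.
    seed : int
        Seed for the surrogate phases.

    Attributes
    ----------
    subject_map_ : DataFrame
        Per subject x ROI: rho, tau1, tau2, norm_latency.
    map_ : DataFrame
        Per ROI: mean rho/tau1/norm_latency, sign_z, p_perm, q_fdr,
        significant.
    """

    def __init__(self, lag_step=0.01, n_perm=10_000, q=0.05, seed=0,
                 fs=100.0):
        self.lag_step = lag_step
        self.n_perm = n_perm
        self.q = q
        self.seed = seed
        self.fs = fs

    def fit(self, envelopes: dict, trials: dict, params: dict, y=None):
        """``envelopes``, ``trials`` and ``params`` are keyed by subject;
        each envelope value is an EnvelopeArray (same ROI set across
        subjects)."""
        subjects = sorted(envelopes)
        first = envelopes[subjects[0]]
        roi_ids = list(first.roi_ids)
        band = first.band
        onset_index = int(round(-first.epoch[0] * self.fs))
        n_time = first.data.shape[2]

        banks, env_epochs = {}, {}
        rows = []
        for s in subjects:
            arr = envelopes[s]
            banks[s] = _PredictionBank(trials[s], params[s], self.fs,
                                       self.lag_step, onset_index, n_time)
            bank = banks[s]
            order = [arr.roi_ids.index(roi) for roi in roi_ids]
            env_epochs[s] = arr.data[order][:, bank.usable]
            rho_mat = bank.correlate_epochs(env_epochs[s])
            rho, idx = _signed_max_rows(rho_mat)
            for r_i, roi in enumerate(roi_ids):
                tau1 = bank.taus[idx[r_i]]
                rows.append({"subject": s, "roi": roi, "band": band,
                             "rho": float(rho[r_i]), "tau1": float(tau1),
                             "tau2": float(bank.t0 - tau1),
                             "norm_latency": float(tau1 / bank.t0)})
        self.subject_map_ = pd.DataFrame(rows)

        group_rows = []
        obs_stat = {}
        for roi in roi_ids:
            sub = self.subject_map_[self.subject_map_["roi"] == roi]
            fz = _fisher_z(sub["rho"].to_numpy())
            z, _, _ = roi_sign_test(fz)
            obs_stat[roi] = float(fz.mean())
            group_rows.append({
                "roi": roi, "band": band, "n_subjects": len(sub),
                "rho": sub["rho"].mean(),
                "abs_rho": sub["rho"].abs().mean(),
                "mean_fisher_z": obs_stat[roi],
                "tau1": sub["tau1"].mean(),
                "norm_latency": sub["norm_latency"].mean(),
                "sign_z": z,
            })
        gmap = pd.DataFrame(group_rows)

        if self.n_perm > 0:
            pvals = permutation_null_pvalues(
                banks, env_epochs, roi_ids, obs_stat, n_iter=self.n_perm,
                seed=self.seed, onset_index=onset_index)
            gmap["p_perm"] = [pvals[r] for r in roi_ids]
            qvals, rej = fdr_correct(gmap["p_perm"].to_numpy(), q=self.q)
            gmap["q_fdr"] = qvals
            gmap["significant"] = rej
        self.map_ = gmap
        return self


def permutation_null_pvalues(banks, env_epochs, roi_ids, observed_stat,
                             n_iter: int = 10_000, seed: int = 0,
                             onset_index: int = 50):
    """Phase-randomisation null for the per-ROI group correlation.

    Each iteration replaces every trial envelope with a phase-randomised
    surrogate (amplitude spectrum preserved, phases scrambled),
    re-estimates every subject's maximum lagged correlation and
    recomputes the group statistic — the mean Fisher-transformed
    correlation across subjects — per ROI. Two-tailed p-values compare
    absolute values with add-one smoothing:
    ``(1 + #{|stat_null| >= |stat_obs|}) / (n_iter + 1)``.

    Parameters
    ----------
    banks : dict subject -> _PredictionBank
    env_epochs : dict subject -> (n_roi, n_trials, n_time) array
        Epoch stacks in ``roi_ids`` order, restricted to the trials the
        bank retained.
    observed_stat : dict roi -> float
        Observed mean Fisher-z correlation per ROI.
    """
    if n_iter < 100:
        import warnings
        warnings.warn(f"n_iter={n_iter} gives a coarse null", stacklevel=2)
    rng = np.random.default_rng(seed)
    subjects = sorted(banks)
    s_obs = np.array([observed_stat[roi] for roi in roi_ids])
    exceed = np.zeros(len(roi_ids), dtype=np.int64)
    for _ in range(n_iter):
        rho_by_subject = np.empty((len(subjects), len(roi_ids)))
        for s_i, s in enumerate(subjects):
            surr = phase_randomize(env_epochs[s], rng=rng)
            rho_mat = banks[s].correlate_epochs(surr)
            rho_by_subject[s_i], _ = _signed_max_rows(rho_mat)
        null_stat = _fisher_z(rho_by_subject).mean(axis=0)
        exceed += np.abs(null_stat) >= np.abs(s_obs)
    return {roi: (1 + int(e)) / (n_iter + 1)
            for roi, e in zip(roi_ids, exceed)}
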