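"""Ground-truth synthetic cohorts for end-to-end pipeline testing.

Emulates the statistical structure the analysis assumes, at desk scale:

* behaviour — accumulator-race choices and RTs over the 2x2
  perceptual x action uncertainty design, with condition-dependent drift
  rates that differ between a control-like and a patient-like group
  (controls react more strongly to action uncertainty) and 10% lognormal
  between-subject parameter jitter;
* envelopes — per-ROI band-power epochs consisting of a negative-going
  accumulation ramp (the model-predicted trajectory for each trial,
  shifted by the ROI's true accumulation-onset latency tau1) embedded in
  1/f plus band-limited oscillatory noise at a controllable SNR. The
  control-like latency profile follows a caudo-rostral gradient (150 ms
  span across the dorsal ROIs); the patient-like profile is flat;
* psychophysics — binomial correct counts at log-spaced coherence levels
  under a Log-Quick observer.

Ground truth (generating parameters, true tau1 per ROI) is carried in the
outputs' metadata and never consulted by the analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lba import (LBAParameters, cell_index, make_design, simulate_lba,
                  trials_to_dataframe)
from .latency import _trajectory_values
from .psychometrics import PsychometricFit, logquick_probability
from .signal import EnvelopeArray, ROISpec, bandpass, hilbert_envelope

__all__ = [
    "CohortSpec", "default_roi_specs", "latency_profile",
    "generate_cohort_behaviour", "generate_envelopes",
    "generate_psychophysics",
]

#: control-like cell drifts (PU low/AU low, low/high, high/low, high/high):
#: strong reaction of accumulation rate to both uncertainty manipulations
_CONTROL_V = (3.5, 2.5, 3.0, 2.0)
#: patient-like drifts: slower overall under low action uncertainty and a
#: smaller low-high action-uncertainty difference
_PATIENT_V = (2.7, 2.3, 2.2, 1.8)


def _default_params(v):
    return LBAParameters(v=np.asarray(v, float), b=1.2, z=0.6, t0=0.35,
                         s=1.0)


def default_roi_specs(n_dorsal: int = 8, n_other: int = 0) -> list[ROISpec]:
    """Dorsal-path ROI set with strictly ordered caudo-rostral positions
    (plus optional non-dorsal fillers)."""
    specs = [ROISpec(roi=f"dorsal{i:02d}", name=f"dorsal region {i}",
                     hemisphere="L", dorsal_path=True,
                     caudo_rostral_position=float(i))
             for i in range(n_dorsal)]
    specs += [ROISpec(roi=f"other{i:02d}", name=f"non-dorsal region {i}",
                      hemisphere="R", dorsal_path=False,
                      caudo_rostral_position=float(-1 - i))
              for i in range(n_other)]
    return specs


def latency_profile(rois: list[ROISpec], kind: str = "gradient",
                    span: float = 0.150, base: float = 0.08) -> dict:
    """True accumulation-onset latency tau1 per ROI.

    ``gradient`` spreads latencies linearly over ``span`` seconds from
    caudal to rostral dorsal ROIs (non-dorsal ROIs get the midpoint);
    ``flat`` gives every ROI the base latency; ``null`` flags no embedded
    signal at all.
    """
    dorsal = sorted([r for r in rois if r.dorsal_path],
                    key=lambda r: r.caudo_rostral_position)
    out = {}
    if kind == "null":
        return {r.roi: None for r in rois}
    for r in rois:
        if kind == "flat" or not r.dorsal_path:
            out[r.roi] = base + (span / 2.0 if kind != "flat" else 0.0)
        else:
            rank = dorsal.index(r) / max(len(dorsal) - 1, 1)
            out[r.roi] = base + span * rank
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_controls: int = 21
    n_patients: int = 17
    n_trials_per_cell: int = 160          # 640 trials per participant
    control_params: LBAParameters = field(
        default_factory=lambda: _default_params(_CONTROL_V))
    patient_params: LBAParameters = field(
        default_factory=lambda: _default_params(_PATIENT_V))
    subject_cv: float = 0.10              # lognormal between-subject jitter
    rois: tuple = field(
        default_factory=lambda: tuple(default_roi_specs(8)))
    latency_kind: str = "gradient"        # gradient | flat | null
    latency_span: float = 0.150
    latency_base: float = 0.08
    snr: float = 2.0                      # ramp amplitude / noise-env SD
    one_over_f_exponent: float = 1.0
    osc_band: tuple = (13.0, 30.0)
    osc_amplitude: float = 1.0
    fs: float = 100.0
    epoch: tuple = (-0.5, 1.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("need at least one subject per group")
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        taus = latency_profile(list(self.rois), self.latency_kind,
                               self.latency_span, self.latency_base)
        t0 = min(self.control_params.t0.min(),
                 self.patient_params.t0.min())
        bad = [r for r, t in taus.items() if t is not None and t >= t0]
        if bad:
            raise ValueError(f"true tau1 >= t0 for ROIs {bad}")


def _jitter_params(params: LBAParameters, cv: float, rng) -> LBAParameters:
    """Lognormal multiplicative jitter (given CV) on v, b, z, t0.

    One factor per parameter: cell-varying parameters (distinct values
    across cells) get independent per-cell factors, shared parameters a
    single factor — jitter must not break the variant structure of the
    generating model.
    """
    sigma = np.sqrt(np.log1p(cv ** 2))

    def jit(arr):
        arr = np.asarray(arr, dtype=float)
        n = len(np.unique(arr))
        if n == 1:
            return arr * rng.lognormal(-sigma ** 2 / 2, sigma)
        return arr * rng.lognormal(-sigma ** 2 / 2, sigma, size=arr.shape)

    b = jit(params.b)
    return replace(params, v=jit(params.v), b=b,
                   z=np.minimum(jit(params.z), 0.95 * b), t0=jit(params.t0))


def generate_cohort_behaviour(spec: CohortSpec) -> pd.DataFrame:
    """Simulate every subject's trials; returns the trial-table schema the
    fitting stage reads plus the per-subject true parameters in ``attrs``."""
    rng = np.random.default_rng(spec.seed)
    frames, truth = [], {}
    groups = ([("control", spec.control_params)] * spec.n_controls
              + [("patient", spec.patient_params)] * spec.n_patients)
    for i, (group, base) in enumerate(groups):
        sid = f"{'c' if group == 'control' else 'p'}{i:03d}"
        params = _jitter_params(base, spec.subject_cv, rng)
        design = make_design(spec.n_trials_per_cell,
                             seed=int(rng.integers(2 ** 31)))
        trials = simulate_lba(params, design,
                              seed=int(rng.integers(2 ** 31)),
                              subject=sid, group=group)
        frames.append(trials_to_dataframe(trials))
        truth[sid] = params
    df = pd.concat(frames, ignore_index=True)
    df.attrs["true_params"] = truth
    return df


def _noise_epochs(rng, n_trials, n_time, fs, exponent, band, osc_amp):
    """1/f plus band-limited Gaussian noise, per trial."""
    freqs = np.fft.rfftfreq(n_time, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_trials, n_time))
    pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * shape, n=n_time,
                        axis=-1)
    pink /= max(pink.std(), 1e-12)
    osc = bandpass(rng.standard_normal((n_trials, n_time)), band, fs)
    osc /= max(osc.std(), 1e-12)
    return pink + osc_amp * osc


def generate_envelopes(spec: CohortSpec, behaviour: pd.DataFrame,
                       subjects=None) -> dict:
    """Per-subject ROI x trial x time envelope arrays with embedded ramps.

    Each trial's envelope is the noise envelope (centred on its baseline
    mean) plus a negative-scaled copy of the model-predicted accumulation
    trajectory shifted by the ROI's true tau1; the ramp amplitude is
    ``snr`` times the noise-envelope SD in the baseline window. True tau1
    values are stored in each array's ``truth`` metadata.
    """
    truth_params = behaviour.attrs.get("true_params", {})
    taus = latency_profile(list(spec.rois), spec.latency_kind,
                           spec.latency_span, spec.latency_base)
    rng = np.random.default_rng(spec.seed + 1)
    fs = spec.fs
    n_time = int(round((spec.epoch[1] - spec.epoch[0]) * fs))
    times = spec.epoch[0] + np.arange(n_time) / fs
    base_mask = (times >= -0.4) & (times < -0.1)
    onset = times >= 0.0

    out = {}
    if subjects is None:
        subjects = sorted(behaviour["subject"].unique())
    for sid in subjects:
        sub = behaviour[behaviour["subject"] == sid].reset_index(drop=True)
        params = truth_params.get(sid)
        if params is None:
            raise ValueError(f"no true parameters for subject {sid}")
        n_trials = len(sub)
        data = np.empty((len(spec.rois), n_trials, n_time))
        for r_i, roi in enumerate(spec.rois):
            noise = _noise_epochs(rng, n_trials, n_time, fs,
                                  spec.one_over_f_exponent, spec.osc_band,
                                  spec.osc_amplitude)
            env = hilbert_envelope(noise)
            env -= env[:, base_mask].mean(axis=1, keepdims=True)
            sigma = float(env[:, base_mask].std())
            tau1 = taus[roi.roi]
            if tau1 is not None:
                # one global scale per ROI: per-trial rescaling would break
                # the cross-trial rank structure the analysis relies on
                trajs = {}
                for t_i in range(n_trials):
                    rt = sub.loc[t_i, "rt"]
                    ci = cell_index(sub.loc[t_i, "pu"], sub.loc[t_i, "au"])
                    v, b, z, t0 = params.cell(ci)
                    if rt <= t0 + 2.0 / fs:
                        continue
                    trajs[t_i] = _trajectory_values(
                        np.minimum(times[onset], rt), rt, v, b, z, t0,
                        len(str(sub.loc[t_i, "options"]).split("|")),
                        min(tau1, t0 - 1.0 / fs))
                excursion = np.median([t.max() - t.min()
                                       for t in trajs.values()])
                scale = spec.snr * sigma / max(excursion, 1e-12)
                for t_i, traj in trajs.items():
                    env[t_i, onset] -= scale * traj
            data[r_i] = env
        out[sid] = EnvelopeArray(
            subject=sid, band="beta", roi_ids=[r.roi for r in spec.rois],
            data=data, fs=fs, epoch=spec.epoch,
            baseline_window=(-0.4, -0.1),
            truth={"tau1": [np.nan if taus[r.roi] is None else taus[r.roi]
                            for r in spec.rois]})
    return out


def generate_psychophysics(fit: PsychometricFit, levels,
                           n_per_level: int = 32, seed: int = 0
                           ) -> pd.DataFrame:
    """Binomial correct counts at each stimulus level under the given
    psychometric observer. 32 trials per level by default, matching the
    training-session design (8 log-spaced levels)."""
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    p = logquick_probability(levels, fit)
    k = rng.binomial(n_per_level, p)
    return pd.DataFrame({"level": levels, "n_correct": k,
                         "n_total": n_per_level})
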