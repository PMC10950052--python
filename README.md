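# lbacascade

Linking decision behaviour to neural oscillations: linear ballistic
accumulator (LBA) modelling of choice/RT data, random-effects Bayesian
model selection, and latency mapping of evidence accumulation in
band-limited cortical power envelopes.

## The problem

In visuomotor decision tasks, perceptual evidence and action intentions
accumulate over time across a cortical hierarchy, and band-limited power
(especially beta, 13–30 Hz) desynchronises as evidence accrues. This
package implements the full analysis cascade needed to study that
process — for example, to compare healthy and patient cohorts performing
a 2×2 design crossing *perceptual uncertainty* (PU: motion-coherence
difficulty, calibrated per subject) with *action uncertainty* (AU: one
vs three valid response options):

1. **Psychometrics** — fit the Log-Quick function
   `P(x) = γ + (1−γ−λ)(1 − 2^(−10^(β(x−α))))` to coherence/accuracy
   counts and invert it to per-subject stimulus levels (90% / 75%
   accuracy points for low / high PU).
2. **Accumulator modelling** — independent accumulators with start point
   ~ Uniform[0, z] and rate ~ Normal(v, s) race to a bound b; RT is the
   winner's passage time plus non-decision time t0. All 15 variants
   (any subset of {v, b, z, t0} varying over the four condition cells)
   are fitted by multi-start maximum likelihood and scored by
   BIC = k·ln(n) − 2·loglik.
3. **Model selection** — random-effects Bayesian model selection on
   −BIC/2 (variational Dirichlet posterior, Monte-Carlo exceedance
   probabilities), plus the between-group posterior
   `P(same model | data) = 1/(1 + exp(logE_split − logE_pooled))`.
4. **Envelopes** — Butterworth band-pass, first-PC ROI reduction,
   Hilbert amplitude, 100 Hz resampling, percent-change baseline
   normalisation.
5. **Latency mapping** — split the non-decision time t0 = τ1 + τ2 by
   maximising the lagged absolute Spearman correlation between
   model-predicted accumulation trajectories and concatenated
   single-trial envelopes; per-ROI sign tests, phase-randomised
   surrogate nulls, Benjamini–Hochberg FDR.
6. **Group statistics** — cluster-corrected permutation tests on
   envelopes, a linear mixed model of band power (PU, AU, Group and
   interactions; subjects nested in ROIs), caudo-rostral gradient
   regression of normalised latencies (τ1/t0), Wilcoxon rank-sum and
   Fisher-exact/odds-ratio contingency tests.

A synthetic-data module generates ground-truth cohorts (behaviour,
envelopes with embedded desynchronisation ramps at controlled SNR,
psychophysics counts) so every stage is testable end to end without any
recordings.

## Worked example

```python
import numpy as np
from lbacascade import LogQuickPsychometric, contingency_odds_ratio
from lbacascade.psychometrics import PsychometricFit
from lbacascade.synthetic import generate_psychophysics
from lbacascade.studies import tau_recovery_study

# calibrate a synthetic observer's coherence thresholds
observer = PsychometricFit(alpha=np.log10(0.25), beta=2.2,
                           gamma=0.25, lamda=0.02)
levels = np.log10(np.logspace(np.log10(0.05), np.log10(0.9), 8))
counts = generate_psychophysics(observer, levels, n_per_level=32, seed=42)
psy = LogQuickPsychometric(chance=0.25, seed=0).fit(
    counts["level"], counts["n_correct"], counts["n_total"])
print(f"threshold alpha = {psy.alpha_:.3f}, slope beta = {psy.beta_:.2f}")
print(f"low-PU coherence  = {10**psy.thresholds_['low_PU']:.3f}")
print(f"high-PU coherence = {10**psy.thresholds_['high_PU']:.3f}")

# recover an embedded caudo-rostral latency gradient at SNR 2
res = tau_recovery_study(n_subjects=5, n_trials_per_cell=40,
                         snr=2.0, seed=3)
print(res["map"][["roi", "rho", "tau1", "true_tau1",
                  "norm_latency"]].round(3).to_string(index=False))
g = res["gradient"]
print(f"gradient slope = {g.slope:.4f}, R^2 = {g.r_squared:.2f}")
```

Output:

```
threshold alpha = -0.663, slope beta = 1.43
low-PU coherence  = 0.497
high-PU coherence = 0.317
     roi    rho  tau1  true_tau1  norm_latency
dorsal00 -0.789 0.076      0.080         0.239
dorsal01 -0.780 0.098      0.101         0.306
dorsal02 -0.775 0.126      0.123         0.395
dorsal03 -0.767 0.142      0.144         0.446
dorsal04 -0.762 0.168      0.166         0.529
dorsal05 -0.745 0.192      0.187         0.604
dorsal06 -0.736 0.216      0.209         0.678
dorsal07 -0.725 0.240      0.230         0.753
gradient slope = 0.0734, R^2 = 1.00
```

The fitted thresholds put the easier (low-uncertainty) condition at
higher coherence; the latency map recovers each region's true
accumulation onset to within a couple of milliseconds (negative ρ:
power *desynchronises* as evidence accumulates), and the 150-ms
caudo-rostral gradient across the eight dorsal regions comes back as a
clean linear trend in normalised latency τ1/t0.

Demographic contingency checks work the same way:

```python
odds, p = contingency_odds_ratio([[10, 7], [13, 8]])  # patients, controls
# odds ratio = 0.88, Fisher p = 1.00
```

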