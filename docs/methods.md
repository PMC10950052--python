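# Methods

This note documents the models and procedures implemented in
`lbacascade`, the numerical choices behind them, and what the synthetic
validation studies do and do not establish.

## Scientific setting

The pipeline links choice/reaction-time behaviour in a 2x2 visuomotor
uncertainty design to the dynamics of band-limited cortical power. Two
factors are crossed: *perceptual uncertainty* (PU; the difficulty of a
motion-coherence discrimination, calibrated per subject from a
psychometric fit) and *action uncertainty* (AU; whether one response
option or three are simultaneously valid). Behaviour is modelled with a
linear ballistic accumulator (LBA) race; competing restrictions of that
model are compared across subjects by random-effects Bayesian model
selection; and the winning model's trial-by-trial predictions are used to
locate, per cortical region, the onset of evidence accumulation inside
band-limited power envelopes — splitting the non-decision time into a
pre-accumulation (sensory encoding, tau1) and a post-accumulation (motor
execution, tau2) component.

## Psychometric calibration

Accuracy as a function of stimulus level x (log10 coherence) follows the
Log-Quick function F(x) = 1 - 2^(-10^(beta(x - alpha))), scaled to
P(x) = gamma + (1 - gamma - lamda) F(x). alpha is the threshold (the
point where F = 1/2), beta the slope, gamma the guess rate and lamda the
lapse rate. Fitting maximises the binomial log-likelihood with 10
Latin-hypercube multi-starts under bounds gamma in [0, chance + 0.1] and
lamda in [0, 0.1]; the bounds are standard lapse-rate practice and
prevent the asymptote/slope trade-off on small datasets. The function is
inverted analytically; the 90% and 75% accuracy points define the low-
and high-PU stimulus levels respectively (low uncertainty is the easier
condition; the pairing is a constructor argument for users who need the
opposite convention).

Treating x as log coherence makes the expression above the standard
Log-Quick form; level lists in coherence units should be log-transformed
at the interface.

## Accumulator model

Each response option is an independent accumulator. On a trial,
activation starts at a level drawn from Uniform[0, z], grows linearly at
a rate drawn from Normal(v, s), and the first accumulator to reach the
bound b determines the response; RT is that passage time plus a constant
non-decision time t0. Only available options engage accumulators (one
under low AU, three under high AU), and all engaged accumulators in a
trial share the cell's parameters. The drift SD s is the scaling
constant, fixed at 1 for all accumulators and conditions. z is
interpreted as the shared upper bound of the start-point distribution;
per-option bias offsets are not modelled.

The first-passage density and distribution use the standard closed
forms for a uniform start point and normal rate. The race likelihood of
a trial with m engaged accumulators and decision time dt = rt - t0 is
f(dt) (1 - F(dt))^(m-1), renormalised by 1 - Phi(-v/s)^m, the
probability that at least one engaged rate draw is positive (a race in
which every draw is negative never terminates; the simulator resamples
such draw sets, and the likelihood conditions on the same event).
Trials with rt <= t0 contribute a log-likelihood floor of -20 rather
than -inf so multi-start search can traverse bad t0 regions. Trials
with RT outside [0.1 s, 2.1 s] are excluded before fitting, as are
responses that are not among the available options (treated as
fast-guess contaminants; switchable).

**Variant space.** Any non-empty subset of {v, b, z, t0} may take a
distinct value in each of the four (PU x AU) cells while the rest are
shared — 15 variants. A variant with f cell-varying parameters fits
3f + 4 scalars (s excluded); this count enters the BIC,
k ln(n) - 2 loglik.

**Optimisation.** Bounded Nelder-Mead, each run started from the best of
`n_presearch` uniform random draws and repeated `n_starts` times
(defaults 100 and 25, mirroring common practice for this model family;
the validation studies use the reduced 20 x 5 schedule, which the
recovery results show is sufficient at these trial counts). Bounds:
v in (0.1, 10), b in (0.1, 5), t0 in (0.05, min RT - 0.01); z is
optimised as a fraction of b in (0.01, 0.95) so b > z holds throughout
the search. The iteration cap (200 per dimension, f/x tolerances 1e-5)
deliberately trades exhaustive convergence of the largest variants for
speed: their BIC penalty per extra cell-varying parameter
(3 ln 640 ~ 19) dwarfs the ~1 log-unit residual underfit, so model
ranking is unaffected. A numba-compiled kernel evaluates the likelihood
when numba is importable; a vectorised numpy path gives identical
results otherwise.

## Random-effects model selection

Per-subject log model evidence is approximated as -BIC/2. Population
model frequencies get a symmetric Dirichlet(1) prior and subject-level
assignments a multinomial draw; the posterior is obtained by the
standard variational update (iterated to 1e-8 on the concentrations,
max 10,000 iterations). Exceedance probabilities — the probability that
a model is more frequent than all competitors — are computed by
Monte-Carlo argmax counts over Dirichlet draws (default 1e6, seeded);
sampling generalises cleanly to 15 models where the two-model normal
shortcut does not. The group log evidence is the variational free-energy
bound.

The between-group question "is the same model valid for both groups?"
compares the free energy of a pooled analysis against the sum of
per-group free energies, combined as
P(same | data) = 1 / (1 + exp(logE_split - logE_pooled)). The
free-energy bound is the default group-evidence approximation; the
alternative (sum of per-subject evidences) was considered and rejected
as it ignores the frequency prior.

## Envelope extraction

Per ROI and trial: 4th-order Butterworth band-pass (beta 13-30 Hz or
gamma 31-90 Hz) applied forward-backward for zero phase; reduction of a
ROI's vertices to their first principal component (unit-norm loadings,
sign aligned to the vertex mean); Hilbert-transform amplitude envelope;
polyphase anti-aliased resampling to 100 Hz; per-trial percent change
against the mean of the -0.4 to -0.1 s baseline. Epochs span -0.5 to
1.5 s around coherence onset (200 samples at 100 Hz).

Numerical conventions: "power" is the Hilbert amplitude, not its square
(a `square=True` switch restores the squared convention — a -50% vs
-75% step for an amplitude-halving signal); filtering and envelope
extraction run at the native rate before downsampling; baseline
statistics are per-trial (per-session baselining would be a one-line
change where envelopes are normalised).

## Latency mapping

For a candidate pre-accumulation latency tau1 on a 10-ms grid
{0, ..., t0}, each trial's predicted activity is the sum over engaged
accumulators of: a constant at the expected start point z/2 on
[0, tau1); a linear rise on [tau1, rt - tau2] where the winner's slope
is rescaled to reach b exactly at the end of accumulation and losers
rise at the cell-mean rate; a constant thereafter. Per-trial realised
rates are unobservable, so cell means stand in, with the winner
constrained by the observed RT — the deterministic mean path the model
implies for that trial.

All of a subject's trial segments from coherence onset to RT are
concatenated, and Spearman's rho is computed between the concatenated
envelope and the concatenated prediction at each tau1; the tau1
maximising |rho| (ties toward smaller tau1) is the ROI's
accumulation-onset latency, with tau2 = t0 - tau1. Concatenation is
essential: ranks are taken over the whole concatenated vector, so the
cross-trial ordering of activity levels is part of the signal, and any
per-trial rescaling or offsetting of the envelope would corrupt it (the
synthetic generator therefore embeds trajectories with a single global
scale per ROI). Because band power *desynchronises* during
accumulation, the correlations of interest are negative; the signed rho
is reported.

**Group inference.** Per ROI, the Fisher-transformed per-subject
correlations are tested against a zero median with a sign test (exact
binomial p; continuity-corrected normal Z reported). The surrogate null
rebuilds the entire statistic 10,000 times (configurable) after phase
randomisation of every trial envelope — amplitude spectrum preserved
exactly, positive-frequency phases i.i.d. uniform, DC and Nyquist bins
untouched — and compares the group-mean Fisher-z correlation per ROI,
two-tailed with add-one smoothing. The correlation itself (not the
sign-test Z) is the permutation statistic: a sign-test Z over n subjects
has at most n/2 + 1 distinct values, which makes permutation p-values
atomic and mis-calibrated against their nominal level, whereas the mean
Fisher-z is continuous and calibrates cleanly (the null-calibration test
verifies uniformity). Benjamini-Hochberg FDR is applied across ROIs and
bands.

## Group statistics

*Cluster permutation test.* Paired t map over subjects within the
0.1-1 s window, cluster-forming at two-tailed alpha = 0.05, cluster mass
= summed t, null from random condition-label sign flips, cluster p =
proportion of permuted maximum |mass| at least the observed. Requires
>= 6 subjects (below that the sign-flip space is too small for p < 0.05
at any reasonable iteration count).

*Power mixed model.* Median band power per subject x ROI x cell is
modelled with fixed effects PU + AU + Group + PU:Group + AU:Group
(treatment coding, low/control reference) and random intercepts for ROI
and for subjects nested within ROI, estimated by maximum likelihood.
Conditional and marginal R2 follow the variance-partition convention
(fixed + random vs fixed variance over total). In a balanced design the
fixed effects coincide with OLS on cell means, which the tests use as an
oracle.

*Latency gradient.* OLS of mean normalised latency (tau1/t0) on the
caudo-rostral position of the dorsal-path ROIs; the slope CI is
bootstrapped over subjects (2000 resamples) when subject-level latencies
are available.

*Rank and contingency tests.* Wilcoxon rank-sum (midrank W of the first
sample, exact p for small tie-free samples) for group latency and power
comparisons, with per-call tail selection; Fisher's exact test plus the
sample odds ratio a*d/(b*c) for 2x2 demographic tables, first row =
group of interest.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
at the study's design values: 2x2 design, 160 trials per cell (640 per
subject), epochs -0.5 to 1.5 s at 100 Hz, an 8-ROI dorsal-path subset
with strictly ordered caudo-rostral positions. Control-like cell drifts
are (3.5, 2.5, 3.0, 2.0) with b = 1.2, z = 0.6, t0 = 0.35 — plausible
magnitudes for this task class; no numeric drift rates are available to
anchor them, so they are stated here and in the config rather than
sourced. Patient-like drifts (2.7, 2.3, 2.2, 1.8) encode the two
qualitative group effects of interest: slower accumulation under low
action uncertainty and a smaller low-high AU difference. Between-subject
variability is 10% CV lognormal on all parameters.

Envelopes are built as: Hilbert envelope of 1/f (exponent 1) plus
band-limited Gaussian oscillatory noise, centred on its baseline mean,
minus a scaled copy of the model-predicted trajectory shifted by the
ROI's true tau1. SNR is defined at envelope level — ramp amplitude over
the noise-envelope SD in the baseline window — because the analysis only
ever sees envelopes. One scale per ROI (the median trajectory excursion)
keeps cross-trial rank structure intact. The control-like latency
profile spans 150 ms across the dorsal ROIs; the patient-like profile is
flat; a null profile embeds nothing. Ground truth is stored in output
metadata and never read by analysis stages.

What the generator does *not* emulate: volume conduction and source
leakage between ROIs, trial-to-trial amplitude nonstationarity,
evoked-response transients at stimulus onset, and any within-trial
coupling between behavioural noise and envelope noise. Passing recovery
tests therefore establish internal consistency of the estimation
chain — not robustness to those real-data confounds.

## Validation studies and problem sizes

The studies in `lbacascade.studies` (also run by `scripts/acceptance.py`
and the test suite) use desk-scale problem sizes chosen to keep each
study in the minutes range while leaving its conclusion unambiguous:

* model recovery — 20 subjects x 640 trials, all 15 variants, 5 starts
  x 20 pre-searches per fit; exceedance of the generating (drift-only)
  variant saturates at 1.000;
* drift recovery — 25 single-subject 600-trial datasets; median per-cell
  relative drift error 3-7%, comfortably inside +/-15%;
* latency recovery — 5 subjects, 160 trials, SNR 2, 8 ROIs; median
  |tau1 error| ~1-2 ms against a 10-ms grid, gradient rank correlation
  1.0;
* null calibration — 12 subjects x 50 signal-free ROIs at 500 surrogate
  iterations (p-values uniform by KS), 1000 all-null BH replicates at
  m = 192, and 400 null cluster-test simulations at 250 permutations
  (family-wise false-positive rate within [0.02, 0.08]).

## Known limitations

* The LBA t0 (and hence the tau1 grid endpoint) is weakly identified
  from 160-trial datasets; latency mapping is only as good as the
  fitted t0. The latency recovery study isolates the mapping stage by
  using the generating parameters.
* -BIC/2 is a large-n approximation to log model evidence; with few
  trials per subject it can misrank closely matched variants.
* The race likelihood assumes engaged accumulators share cell
  parameters; option-specific drift or bias would require extending the
  parameterisation.
* Exceedance probabilities carry Monte-Carlo error ~0.005 at 1e6 draws;
  protected exceedance (Bayes omnibus risk) is not implemented.
* MixedLM variance components can hit zero on small ROI sets, making
  intercept CIs slightly anticonservative there.
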