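"""Log-Quick psychometric function: evaluation, maximum-likelihood fitting,
and analytic inversion to coherence thresholds.

Accuracy as a function of motion coherence is modelled with the Quick
function on a log-coherence axis,

    F(x) = 1 - 2^(-10^(beta * (x - alpha))),

scaled to the task's guess and lapse rates,

    P(x) = gamma + (1 - gamma - lamda) * F(x),

where ``x`` is log10 coherence, ``alpha`` the threshold (the point where
``F = 1/2``), ``beta`` the slope, ``gamma`` the lower asymptote (chance
performance) and ``lamda`` the lapse rate. Per-subject task difficulty is
set by inverting the fitted curve at two target accuracies (by default the
75% and 90% points), yielding the coherences used for the high and low
perceptual-uncertainty conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator

__all__ = [
    "PsychometricFit",
    "logquick_probability",
    "coherence_for_accuracy",
    "fit_psychometric",
    "LogQuickPsychometric",
]


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted Log-Quick parameters.

    Attributes
    ----------
    alpha : float
        Threshold on the (log-coherence) x axis.
    beta : float
        Slope; must be positive.
    gamma : float
        Guess rate (lower asymptote), in [0, 1).
    lamda : float
        Lapse rate, in [0, 1); controls the upper asymptote ``1 - lamda``.
    chance : float
        Task chance level, used only to bound ``gamma`` during fitting.
    loglik : float
        Binomial log-likelihood at the fitted parameters (nan if the fit
        was constructed by hand).
    boundary_warning : bool
        True when a fitted parameter landed on a bound (degenerate data).
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    lamda: float = 0.0
    chance: float = 0.25
    loglik: float = field(default=float("nan"), compare=False)
    boundary_warning: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("alpha and beta must be finite")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0 <= self.gamma < 1) or not (0 <= self.lamda < 1):
            raise ValueError("gamma and lamda must lie in [0, 1)")
        if self.gamma + self.lamda >= 1:
            raise ValueError("gamma + lamda must be < 1")


def logquick_probability(x, fit: PsychometricFit):
    """Probability of a correct response at stimulus level ``x``.

    Vectorised over ``x``. The output lies in ``[gamma, 1 - lamda]`` and is
    strictly increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    flog = 1.0 - np.exp2(-np.power(10.0, fit.beta * (x - fit.alpha)))
    return fit.gamma + (1.0 - fit.gamma - fit.lamda) * flog


def coherence_for_accuracy(fit: PsychometricFit, p_target: float) -> float:
    """Invert the psychometric function: the ``x`` with ``P(x) = p_target``.

    ``p_target`` must lie strictly inside the attainable range
    ``(gamma, 1 - lamda)``. The inversion is analytic and round-trips with
    :func:`logquick_probability` to ~1e-10.
    """
    lo, hi = fit.gamma, 1.0 - fit.lamda
    if not (lo < p_target < hi):
        raise ValueError(
            f"p_target={p_target} outside the attainable range ({lo}, {hi})"
        )
    flog = (p_target - fit.gamma) / (1.0 - fit.gamma - fit.lamda)
    # F = 1 - 2^(-10^(beta (x - alpha)))  =>  10^(beta (x-alpha)) = -log2(1-F)
    return fit.alpha + np.log10(-np.log2(1.0 - flog)) / fit.beta


def _neg_loglik(theta, x, k, n):
    fit = PsychometricFit(*theta)
    p = logquick_probability(x, fit)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


class LogQuickPsychometric(BaseEstimator):
    """Maximum-likelihood Log-Quick psychometric fit.

    Fits (alpha, beta, gamma, lamda) to per-level correct counts by
    maximising the binomial log-likelihood, with multi-start local
    optimisation from Latin-hypercube draws inside the parameter bounds.

    Parameters
    ----------
    chance : float
        Task chance level; bounds the guess rate at ``chance + 0.1``.
    max_lapse : float
        Upper bound on the lapse rate.
    n_starts : int
        Number of Latin-hypercube starting points.
    seed : int
        Seed for the start-point draws.
    low_p, high_p : float
        Target accuracies defining the low / high perceptual-uncertainty
        coherences (``thresholds_``). The easier condition (low
        uncertainty) maps to the higher accuracy point by default; pass
        swapped values to use the opposite pairing.
    """

    def __init__(self, chance=0.25, max_lapse=0.1, n_starts=10, seed=0,
                 low_p=0.90, high_p=0.75):
        self.chance = chance
        self.max_lapse = max_lapse
        self.n_starts = n_starts
        self.seed = seed
        self.low_p = low_p
        self.high_p = high_p

    def fit(self, levels, n_correct, n_total):
        """Fit to count data; ``levels`` are on the (log) stimulus axis."""
        x = np.asarray(levels, dtype=float)
        k = np.asarray(n_correct, dtype=float)
        n = np.asarray(n_total, dtype=float)
        if not (x.shape == k.shape == n.shape):
            raise ValueError("levels, n_correct and n_total must share a shape")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(k))
                and np.all(np.isfinite(n))):
            raise ValueError("non-finite inputs")
        if np.any(k > n) or np.any(k < 0):
            raise ValueError("need 0 <= n_correct <= n_total")
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct stimulus levels")

        span = x.max() - x.min()
        bounds = [
            (x.min() - span, x.max() + span),          # alpha
            (0.05, 20.0),                              # beta
            (0.0, min(self.chance + 0.1, 0.999)),      # gamma
            (0.0, self.max_lapse),                     # lamda
        ]
        sampler = qmc.LatinHypercube(d=4, seed=self.seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        starts = lo + sampler.random(self.n_starts) * (hi - lo)
        # anchor one start at a data-driven guess
        starts[0] = [np.median(x), 2.0, self.chance, 0.02]

        best = None
        for theta0 in starts:
            res = minimize(_neg_loglik, theta0, args=(x, k, n),
                           method="Nelder-Mead", bounds=bounds,
                           options={"maxiter": 4000, "xatol": 1e-7,
                                    "fatol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
        theta = np.clip(best.x, lo, hi)
        on_boundary = bool(np.any(np.isclose(theta, lo, atol=1e-9)
                                  & (lo != 0.0))
                           | np.isclose(theta[1], hi[1], atol=1e-6))
        degenerate = bool(np.all(k == n) or np.all(k == 0))
        if degenerate:
            warnings.warn("degenerate (all-correct or all-wrong) data; "
                          "fit lies on a parameter boundary", stacklevel=2)
        self.fit_ = PsychometricFit(*theta, chance=self.chance,
                                    loglik=-best.fun,
                                    boundary_warning=on_boundary or degenerate)
        self.alpha_, self.beta_ = theta[0], theta[1]
        self.gamma_, self.lamda_ = theta[2], theta[3]
        self.loglik_ = -best.fun
        def _threshold(p):
            lo_, hi_ = self.fit_.gamma, 1.0 - self.fit_.lamda
            if not (lo_ < p < hi_):
                return float("nan")  # target outside the attainable range
            return coherence_for_accuracy(self.fit_, p)

        self.thresholds_ = {"low_PU": _threshold(self.low_p),
                            "high_PU": _threshold(self.high_p)}
        return self

    def predict_proba(self, x):
        return logquick_probability(x, self.fit_)

    def inverse(self, p_target: float) -> float:
        return coherence_for_accuracy(self.fit_, p_target)

    def to_record(self) -> dict:
        """JSON-ready summary of the fit."""
        return {
            "alpha": self.alpha_, "beta": self.beta_,
            "gamma": self.gamma_, "lamda": self.lamda_,
            "loglik": self.loglik_,
            "thresholds": dict(self.thresholds_),
        }


def fit_psychometric(levels, n_correct, n_total, chance=0.25, **kwargs):
    """Functional wrapper over :class:`LogQuickPsychometric`.

    Returns ``(PsychometricFit, loglik)``.
    """
    est = LogQuickPsychometric(chance=chance, **kwargs).fit(
        levels, n_correct, n_total)
    return est.fit_, est.loglik_
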