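"""Random-effects Bayesian model selection across subjects.

Model frequencies in the population are given a Dirichlet prior and each
subject's model assignment a multinomial draw from those frequencies; a
variational update (Stephan-style random-effects BMS) yields the Dirichlet
posterior over frequencies from a subjects x models matrix of log model
evidences (here -BIC/2). Exceedance probabilities — the probability that a
model is more frequent than every competitor — are computed by Monte-Carlo
sampling of the Dirichlet posterior.

The between-group question "do both groups use the same model?" is decided
by comparing the evidence of a pooled random-effects analysis (same
frequencies in both groups) against the sum of per-group evidences
(different frequencies), combined through a logistic posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "BMSResult", "GroupComparisonResult",
    "rfx_bms", "group_model_posterior", "DirichletModelSelection",
]


@dataclass(frozen=True)
class BMSResult:
    """Posterior of the random-effects model-selection analysis."""

    alpha_posterior: np.ndarray        # Dirichlet concentration per model
    expected_frequencies: np.ndarray   # alpha_k / sum(alpha)
    exceedance_probabilities: np.ndarray
    group_log_evidence: float          # variational free-energy bound
    assignments: np.ndarray            # subjects x models posterior g_nk


@dataclass(frozen=True)
class GroupComparisonResult:
    """Same-model-in-both-groups posterior."""

    log_evidence_pooled: float
    log_evidence_split: float
    posterior_same_model: float
    pooled: BMSResult
    per_group: tuple


def _free_energy(lme, g, alpha, alpha0):
    """Variational bound on the log evidence of the random-effects model."""
    e_ln_r = digamma(alpha) - digamma(alpha.sum())
    acc = float(np.sum(g * (lme + e_ln_r)))
    ent_m = -float(np.sum(g * np.log(np.maximum(g, 1e-300))))
    ln_b = lambda a: float(np.sum(gammaln(a)) - gammaln(np.sum(a)))
    # E_q[ln p(r)] - E_q[ln q(r)]
    kl_r = (ln_b(alpha) - ln_b(alpha0)
            + float(np.dot(alpha0 - alpha, e_ln_r)))
    return acc + ent_m + kl_r


def rfx_bms(log_evidence, alpha0: float = 1.0, n_samples: int = 1_000_000,
            seed: int = 0, tol: float = 1e-8, max_iter: int = 10_000
            ) -> BMSResult:
    """Random-effects BMS on a subjects x models log-evidence matrix.

    Parameters
    ----------
    log_evidence : array, shape (n_subjects, n_models)
        Per-subject log model evidence (-BIC/2 when approximated from BIC).
    alpha0 : float
        Symmetric Dirichlet prior concentration.
    n_samples : int
        Dirichlet Monte-Carlo draws for the exceedance probabilities.
    seed : int
        Seed for the exceedance sampling.

    Returns
    -------
    BMSResult
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("log_evidence must be subjects x models with >= 2 "
                         "models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("non-finite log evidence")
    n_sub, n_mod = lme.shape
    if n_sub < 2:
        warnings.warn("single subject: random-effects posterior is "
                      "degenerate", stacklevel=2)

    a0 = np.full(n_mod, float(alpha0))
    alpha = a0.copy()
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError(
            f"variational update did not converge in {max_iter} iterations "
            f"(last concentration {alpha})")

    freqs = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    # sample in manageable blocks to bound memory at large n_samples
    counts = np.zeros(n_mod, dtype=np.int64)
    remaining = int(n_samples)
    while remaining > 0:
        block = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=block)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=n_mod)
        remaining -= block
    xp = counts / float(n_samples)
    fe = _free_energy(lme, g, alpha, a0)
    return BMSResult(alpha_posterior=alpha, expected_frequencies=freqs,
                     exceedance_probabilities=xp, group_log_evidence=fe,
                     assignments=g)


def group_model_posterior(log_evidence_controls, log_evidence_patients,
                          n_samples: int = 1_000_000, seed: int = 0
                          ) -> GroupComparisonResult:
    """Posterior probability that both groups share the same model.

    Runs the random-effects analysis on the pooled subjects (same
    frequencies hypothesis) and separately per group (different
    frequencies); the split evidence is the sum of the group log
    evidences. The posterior is the logistic of the evidence difference:

        P(same | data) = 1 / (1 + exp(logE_split - logE_pooled)).
    """
    lc = np.asarray(log_evidence_controls, dtype=float)
    lp = np.asarray(log_evidence_patients, dtype=float)
    if lc.shape[1] != lp.shape[1]:
        raise ValueError("groups must share the model axis")
    pooled = rfx_bms(np.vstack([lc, lp]), n_samples=n_samples, seed=seed)
    bc = rfx_bms(lc, n_samples=n_samples, seed=seed + 1)
    bp = rfx_bms(lp, n_samples=n_samples, seed=seed + 2)
    le_pooled = pooled.group_log_evidence
    le_split = bc.group_log_evidence + bp.group_log_evidence
    # logistic of the log-evidence difference, computed stably
    d = le_split - le_pooled
    post = 1.0 / (1.0 + np.exp(d)) if d < 500 else 0.0
    return GroupComparisonResult(log_evidence_pooled=le_pooled,
                                 log_evidence_split=le_split,
                                 posterior_same_model=float(post),
                                 pooled=pooled, per_group=(bc, bp))


class DirichletModelSelection(BaseEstimator):
    """Estimator interface to :func:`rfx_bms`.

    ``fit(log_evidence)`` stores ``alpha_``, ``frequencies_``,
    ``exceedance_`` and ``log_evidence_``.
    """

    def __init__(self, alpha0=1.0, n_samples=1_000_000, seed=0, tol=1e-8):
        self.alpha0 = alpha0
        self.n_samples = n_samples
        self.seed = seed
        self.tol = tol

    def fit(self, log_evidence, y=None):
        res = rfx_bms(log_evidence, alpha0=self.alpha0,
                      n_samples=self.n_samples, seed=self.seed, tol=self.tol)
        self.result_ = res
        self.alpha_ = res.alpha_posterior
        self.frequencies_ = res.expected_frequencies
        self.exceedance_ = res.exceedance_probabilities
        self.log_evidence_ = res.group_log_evidence
        return self

    def to_record(self) -> dict:
        return {
            "alpha": self.alpha_.tolist(),
            "frequencies": self.frequencies_.tolist(),
            "exceedance": self.exceedance_.tolist(),
            "log_evidence": self.log_evidence_,
        }
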