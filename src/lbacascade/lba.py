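"""Linear ballistic accumulator (LBA) race model.

Each response option is an independent accumulator whose activation starts
at a level drawn from Uniform[0, z], rises linearly at a rate drawn from
Normal(v, s), and triggers the response when it reaches the bound b. The
first accumulator to reach the bound wins the race; observed RT is the
winner's first-passage time plus a constant non-decision time t0. Within a
trial only the accumulators of the *available* options are engaged (one
option under low action uncertainty, three under high).

Parameters may be shared across the four condition cells of the 2x2
(perceptual x action uncertainty) design or take a distinct value per cell;
the 15 non-empty subsets of {v, b, z, t0} allowed to vary define the model
variant space. The drift-rate standard deviation s is the scaling constant,
fixed at 1.

Closed-form first-passage density/distribution, the defective race
likelihood (renormalised for all-negative drift draws), forward simulation,
multi-start maximum-likelihood fitting and BIC all live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from sklearn.base import BaseEstimator

__all__ = [
    "LBAParameters", "ModelVariant", "TrialRecord",
    "lba_fpt_pdf", "lba_fpt_cdf", "lba_race_loglik",
    "simulate_lba", "make_design", "enumerate_variants", "variant_index",
    "fit_lba", "bic", "fit_cohort_bics", "LBAModel",
    "CELLS", "cell_index", "trials_to_arrays", "trials_to_dataframe",
    "filter_trials",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: canonical ordering of the four condition cells (PU level, AU level)
CELLS = (("low", "low"), ("low", "high"), ("high", "low"), ("high", "high"))
_CELL_LOOKUP = {c: i for i, c in enumerate(CELLS)}

_PARAM_ORDER = ("v", "b", "z", "t0")


def cell_index(pu: str, au: str) -> int:
    """Canonical 0..3 index of a (PU, AU) condition cell."""
    return _CELL_LOOKUP[(pu, au)]


@dataclass(frozen=True)
class ModelVariant:
    """Which parameters take distinct values in each condition cell."""

    free_set: frozenset

    def __post_init__(self):
        fs = frozenset(self.free_set)
        if not fs or not fs <= set(_PARAM_ORDER):
            raise ValueError(f"free_set must be a non-empty subset of "
                             f"{_PARAM_ORDER}, got {set(self.free_set)}")
        object.__setattr__(self, "free_set", fs)

    @property
    def name(self) -> str:
        return "+".join(p for p in _PARAM_ORDER if p in self.free_set)

    @property
    def n_free_scalars(self) -> int:
        """Number of fitted scalars: 4 per cell-varying parameter, 1 per
        shared parameter (s excluded, fixed)."""
        k = len(self.free_set)
        return 4 * k + (4 - k)


def enumerate_variants() -> list[ModelVariant]:
    """All 15 variants, ordered by subset size then parameter order."""
    out = []
    for r in range(1, 5):
        for combo in combinations(_PARAM_ORDER, r):
            out.append(ModelVariant(frozenset(combo)))
    return out


def variant_index(name: str) -> int:
    """Position of a variant (e.g. ``"v"`` or ``"v+b"``) in the canonical
    enumeration."""
    names = [m.name for m in enumerate_variants()]
    return names.index(name)


@dataclass(frozen=True)
class LBAParameters:
    """Accumulator parameters, broadcast over the four condition cells.

    Each of ``v``, ``b``, ``z``, ``t0`` may be a scalar (shared) or a
    length-4 array (one value per cell in :data:`CELLS` order). ``z`` is
    the upper bound of the uniform start-point distribution and must be
    below ``b`` cell-wise; ``s`` is the drift SD scaling constant.
    """

    v: np.ndarray
    b: np.ndarray
    z: np.ndarray
    t0: np.ndarray
    s: float = 1.0

    def __post_init__(self):
        for nm in ("v", "b", "z", "t0"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, nm), dtype=float), (4,)).copy()
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {nm}")
            object.__setattr__(self, nm, arr)
        if self.s <= 0:
            raise ValueError("s must be positive")
        if np.any(self.v <= 0):
            raise ValueError("drift rates must be positive")
        if np.any(self.b <= self.z) or np.any(self.z < 0):
            raise ValueError("need b > z >= 0 in every cell")
        if np.any(self.t0 < 0):
            raise ValueError("t0 must be non-negative")

    def cell(self, i: int) -> tuple[float, float, float, float]:
        return self.v[i], self.b[i], self.z[i], self.t0[i]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural trial."""

    subject: str
    group: str          # "control" | "patient"
    pu: str             # "low" | "high"
    au: str             # "low" | "high"
    available_options: frozenset
    response: int
    rt: float

    def __post_init__(self):
        object.__setattr__(self, "available_options",
                           frozenset(self.available_options))
        if len(self.available_options) not in (1, 3):
            raise ValueError("1 or 3 options must be available")


# ---------------------------------------------------------------------------
# first-passage time distribution of a single accumulator
# ---------------------------------------------------------------------------

def _phi(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


def lba_fpt_pdf(t, v, s, b, z):
    """First-passage density at decision time ``t`` for one accumulator.

    Start point ~ Uniform[0, z], rate ~ Normal(v, s), bound b. The density
    is defective: its total mass is P(rate > 0) when z > 0 ... strictly the
    mass of finite passage. Returns 0 for t <= 0.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(v)), dtype=float)
    pos = t > 0
    if not np.any(pos):
        return out if out.shape else float(out)
    tp = np.broadcast_to(t, out.shape)[pos]
    vv = np.broadcast_to(np.asarray(v, float), out.shape)[pos] \
        if np.ndim(v) else v
    bb = np.broadcast_to(np.asarray(b, float), out.shape)[pos] \
        if np.ndim(b) else b
    zz = np.broadcast_to(np.asarray(z, float), out.shape)[pos] \
        if np.ndim(z) else z
    ts = tp * s
    if np.ndim(zz) == 0 and zz < 1e-9:
        # degenerate start point: passage time b / rate
        h = (bb / tp - vv) / s
        out[pos] = bb / (s * tp * tp) * _phi(h)
        return out if out.shape else float(out)
    h1 = (bb - zz - tp * vv) / ts
    h2 = (bb - tp * vv) / ts
    dens = (-vv * ndtr(h1) + s * _phi(h1) + vv * ndtr(h2) - s * _phi(h2)) / zz
    out[pos] = np.maximum(dens, 0.0)
    return out if out.shape else float(out)


def lba_fpt_cdf(t, v, s, b, z):
    """First-passage distribution function; see :func:`lba_fpt_pdf`."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(v)), dtype=float)
    pos = t > 0
    if not np.any(pos):
        return out if out.shape else float(out)
    tp = np.broadcast_to(t, out.shape)[pos]
    vv = np.broadcast_to(np.asarray(v, float), out.shape)[pos] \
        if np.ndim(v) else v
    bb = np.broadcast_to(np.asarray(b, float), out.shape)[pos] \
        if np.ndim(b) else b
    zz = np.broadcast_to(np.asarray(z, float), out.shape)[pos] \
        if np.ndim(z) else z
    ts = tp * s
    if np.ndim(zz) == 0 and zz < 1e-9:
        out[pos] = 1.0 - ndtr((bb / tp - vv) / s)
        return out if out.shape else float(out)
    h1 = (bb - zz - tp * vv) / ts
    h2 = (bb - tp * vv) / ts
    cdf = (1.0
           + (bb - zz - tp * vv) / zz * ndtr(h1)
           - (bb - tp * vv) / zz * ndtr(h2)
           + ts / zz * (_phi(h1) - _phi(h2)))
    out[pos] = np.clip(cdf, 0.0, 1.0)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# race likelihood
# ---------------------------------------------------------------------------

_LOG_FLOOR = -20.0  # log-contribution for trials with rt <= t0

try:  # optional numba acceleration of the fitting hot path
    import math

    from numba import njit

    @njit(cache=True, fastmath=True)
    def _race_loglik_kernel(rt, cell_idx, n_opts, v, b, z, t0, s):
        inv_sqrt2 = 0.7071067811865476
        inv_sqrt2pi = 0.3989422804014327
        total = 0.0
        for i in range(rt.shape[0]):
            c = cell_idx[i]
            dt = rt[i] - t0[c]
            if dt <= 1e-9:
                total += _LOG_FLOOR
                continue
            vc, bc = v[c], b[c]
            zc = z[c] if z[c] > 1e-9 else 1e-9
            ts = dt * s
            h1 = (bc - zc - dt * vc) / ts
            h2 = (bc - dt * vc) / ts
            n1 = 0.5 * (1.0 + math.erf(h1 * inv_sqrt2))
            n2 = 0.5 * (1.0 + math.erf(h2 * inv_sqrt2))
            p1 = inv_sqrt2pi * math.exp(-0.5 * h1 * h1)
            p2 = inv_sqrt2pi * math.exp(-0.5 * h2 * h2)
            f = (-vc * n1 + s * p1 + vc * n2 - s * p2) / zc
            if f < 0.0:
                f = 0.0
            cdf = (1.0 + (bc - zc - dt * vc) / zc * n1
                   - (bc - dt * vc) / zc * n2 + ts / zc * (p1 - p2))
            if cdf < 0.0:
                cdf = 0.0
            elif cdf > 1.0:
                cdf = 1.0
            surv = 1.0 - cdf
            m = n_opts[i]
            pneg = 0.5 * (1.0 + math.erf(-vc / s * inv_sqrt2))
            contrib = (math.log(max(f, 1e-300))
                       + (m - 1) * math.log(max(surv, 1e-300))
                       - math.log(1.0 - pneg ** m))
            total += max(contrib, _LOG_FLOOR)
        return total

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _race_loglik_arrays(rt, cell_idx, n_opts, v, b, z, t0, s=1.0):
    """Vectorised race log-likelihood.

    ``v, b, z, t0`` are length-4 per-cell arrays; all engaged accumulators
    in a trial share the cell parameters, so the winner density is
    pdf(dt) * (1 - cdf(dt))**(m-1), renormalised by the probability that at
    least one engaged drift draw is positive. The density and distribution
    terms are evaluated inline so the normal cdf/pdf factors are shared.
    """
    if _HAVE_NUMBA:
        return float(_race_loglik_kernel(
            rt, cell_idx.astype(np.int64), n_opts.astype(np.int64),
            np.ascontiguousarray(v, dtype=np.float64),
            np.ascontiguousarray(b, dtype=np.float64),
            np.ascontiguousarray(z, dtype=np.float64),
            np.ascontiguousarray(t0, dtype=np.float64), float(s)))
    vi, bi, zi, ti = v[cell_idx], b[cell_idx], z[cell_idx], t0[cell_idx]
    dt = rt - ti
    ok = dt > 1e-9
    ll = np.full(rt.shape, _LOG_FLOOR)
    if np.any(ok):
        dtk, vk, bk = dt[ok], vi[ok], bi[ok]
        zk = np.maximum(zi[ok], 1e-9)
        ts = dtk * s
        h1 = (bk - zk - dtk * vk) / ts
        h2 = (bk - dtk * vk) / ts
        n1, n2 = ndtr(h1), ndtr(h2)
        p1, p2 = _phi(h1), _phi(h2)
        f = np.maximum((-vk * n1 + s * p1 + vk * n2 - s * p2) / zk, 0.0)
        cdf = (1.0 + (bk - zk - dtk * vk) / zk * n1
               - (bk - dtk * vk) / zk * n2 + ts / zk * (p1 - p2))
        surv = 1.0 - np.clip(cdf, 0.0, 1.0)
        m = n_opts[ok]
        p_all_neg = ndtr(-vk / s) ** m
        contrib = (np.log(np.maximum(f, 1e-300))
                   + (m - 1) * np.log(np.maximum(surv, 1e-300))
                   - np.log1p(-p_all_neg))
        ll[ok] = np.maximum(contrib, _LOG_FLOOR)
    return float(np.sum(ll))


def trials_to_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert trials (DataFrame or TrialRecord list) to
    ``(rt, cell_idx, n_opts)`` arrays."""
    if isinstance(trials, pd.DataFrame):
        rt = trials["rt"].to_numpy(dtype=float)
        cell = np.array([cell_index(p, a)
                         for p, a in zip(trials["pu"], trials["au"])])
        if "options" in trials.columns:
            n_opts = np.array([len(str(o).split("|"))
                               for o in trials["options"]])
        else:
            n_opts = trials["n_options"].to_numpy(dtype=int)
    else:
        rt = np.array([tr.rt for tr in trials], dtype=float)
        cell = np.array([cell_index(tr.pu, tr.au) for tr in trials])
        n_opts = np.array([len(tr.available_options) for tr in trials])
    return rt, cell, n_opts


def lba_race_loglik(trials, params: LBAParameters,
                    variant: ModelVariant | None = None) -> float:
    """Log-likelihood of a trial set under the race model.

    ``variant`` is accepted for interface symmetry but the cell structure
    is carried entirely by ``params`` (shared parameters are already
    broadcast to the four cells).
    """
    rt, cell, n_opts = trials_to_arrays(trials)
    if rt.size == 0:
        raise ValueError("empty trial list")
    if not np.all(np.isfinite(rt)):
        raise ValueError("non-finite RT")
    return _race_loglik_arrays(rt, cell, n_opts,
                               params.v, params.b, params.z, params.t0,
                               s=params.s)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def make_design(n_per_cell: int, seed: int = 0) -> list:
    """A balanced 2x2 design: ``n_per_cell`` trials per condition cell.

    Low action uncertainty trials offer one option, high three (drawn at
    random from the four buttons).
    """
    rng = np.random.default_rng(seed)
    design = []
    for pu, au in CELLS:
        for _ in range(n_per_cell):
            k = 1 if au == "low" else 3
            opts = frozenset(rng.choice(4, size=k, replace=False).tolist())
            design.append((pu, au, opts))
    return design


def simulate_lba(params: LBAParameters, design, seed: int = 0,
                 subject: str = "s0", group: str = "control",
                 variant: ModelVariant | None = None) -> list[TrialRecord]:
    """Simulate one trial per design row ``(pu, au, available_options)``.

    Start points are Uniform[0, z]; rates Normal(v, s) with all-negative
    draw sets resampled (an all-negative race never terminates). RT is the
    winning accumulator's passage time plus t0.
    """
    rng = np.random.default_rng(seed)
    out = []
    for pu, au, opts in design:
        ci = cell_index(pu, au)
        v, b, z, t0 = params.cell(ci)
        opts = sorted(opts)
        m = len(opts)
        while True:
            rates = rng.normal(v, params.s, size=m)
            if np.any(rates > 0):
                break
        starts = rng.uniform(0.0, z, size=m) if z > 0 else np.zeros(m)
        with np.errstate(divide="ignore"):
            finish = np.where(rates > 0, (b - starts) / rates, np.inf)
        w = int(np.argmin(finish))
        out.append(TrialRecord(subject=subject, group=group, pu=pu, au=au,
                               available_options=frozenset(opts),
                               response=opts[w],
                               rt=float(finish[w] + t0)))
    return out


def trials_to_dataframe(trials: list[TrialRecord]) -> pd.DataFrame:
    """Trial records -> the CSV schema the fitting stage reads."""
    return pd.DataFrame({
        "subject": [t.subject for t in trials],
        "group": [t.group for t in trials],
        "pu": [t.pu for t in trials],
        "au": [t.au for t in trials],
        "options": ["|".join(str(o) for o in sorted(t.available_options))
                    for t in trials],
        "response": [t.response for t in trials],
        "rt": [t.rt for t in trials],
    })


def filter_trials(trials: pd.DataFrame, rt_window=(0.1, 2.1),
                  exclude_errors: bool = True) -> pd.DataFrame:
    """Apply the RT inclusion window and (optionally) drop trials whose
    response is not among the available options (fast-guess contaminants)."""
    lo, hi = rt_window
    keep = (trials["rt"] >= lo) & (trials["rt"] <= hi)
    if exclude_errors and "options" in trials.columns:
        valid = [str(r) in str(o).split("|")
                 for r, o in zip(trials["response"], trials["options"])]
        keep &= np.asarray(valid)
    return trials.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, ``k ln(n) - 2 loglik``."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return k * np.log(n) - 2.0 * loglik


def _theta_layout(variant: ModelVariant):
    """(name, n_values) per parameter in canonical order."""
    return [(p, 4 if p in variant.free_set else 1) for p in _PARAM_ORDER]


def _unpack_theta(theta, variant: ModelVariant):
    """theta -> per-cell (v, b, z, t0) arrays. z is optimised as a fraction
    of the cell bound so the b > z constraint holds throughout the search."""
    vals = {}
    i = 0
    for name, nv in _theta_layout(variant):
        vals[name] = np.broadcast_to(theta[i:i + nv], (4,))
        i += nv
    v = np.asarray(vals["v"], float)
    b = np.asarray(vals["b"], float)
    z = np.asarray(vals["z"], float) * b   # z stored as fraction of b
    t0 = np.asarray(vals["t0"], float)
    return v, b, z, t0


def _fit_bounds(variant: ModelVariant, max_t0: float):
    base = {"v": (0.1, 10.0), "b": (0.1, 5.0), "z": (0.01, 0.95),
            "t0": (0.05, max(max_t0, 0.06))}
    bounds = []
    for name, nv in _theta_layout(variant):
        bounds.extend([base[name]] * nv)
    return bounds


def fit_lba(trials, variant: ModelVariant, n_starts: int = 25,
            n_presearch: int = 100, seed: int = 0,
            rt_window=(0.1, 2.1), prefilter: bool = True):
    """Multi-start maximum-likelihood fit of one model variant.

    Each of ``n_starts`` local optimisations (bounded Nelder-Mead) starts
    from the best of ``n_presearch`` uniform random draws within bounds.
    Deterministic given ``seed``. Returns ``(LBAParameters, loglik)``.
    """
    if isinstance(trials, pd.DataFrame) and prefilter:
        trials = filter_trials(trials, rt_window=rt_window)
    rt, cell, n_opts = trials_to_arrays(trials)
    if rt.size == 0:
        raise ValueError("no trials to fit")
    if rt.size < 50:
        import warnings
        warnings.warn(f"only {rt.size} trials; estimates may be unstable",
                      stacklevel=2)

    rt = np.ascontiguousarray(rt, dtype=np.float64)
    cell_i = cell.astype(np.int64)
    n_opts_i = n_opts.astype(np.int64)

    if _HAVE_NUMBA:
        def nll(theta):
            v, b, z, t0 = _unpack_theta(np.asarray(theta), variant)
            if np.any(v <= 0) or np.any(b <= 0):
                return 1e12
            return -_race_loglik_kernel(
                rt, cell_i, n_opts_i, np.ascontiguousarray(v),
                np.ascontiguousarray(b), np.ascontiguousarray(z),
                np.ascontiguousarray(t0), 1.0)
    else:
        def nll(theta):
            v, b, z, t0 = _unpack_theta(np.asarray(theta), variant)
            if np.any(v <= 0) or np.any(b <= 0):
                return 1e12
            return -_race_loglik_arrays(rt, cell, n_opts, v, b, z, t0)

    bounds = _fit_bounds(variant, max_t0=float(rt.min()) - 0.01)
    lo = np.array([b_[0] for b_ in bounds])
    hi = np.array([b_[1] for b_ in bounds])
    rng = np.random.default_rng(seed)

    best_fun, best_x, failures = np.inf, None, []
    for _ in range(n_starts):
        draws = lo + rng.random((n_presearch, lo.size)) * (hi - lo)
        f0 = np.array([nll(d) for d in draws])
        x0 = draws[int(np.argmin(f0))]
        res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds,
                       options={"maxiter": 200 * lo.size, "fatol": 1e-5,
                                "xatol": 1e-5, "adaptive": lo.size > 8})
        if np.isfinite(res.fun):
            if res.fun < best_fun:
                best_fun, best_x = res.fun, res.x
        else:
            failures.append(res.message)
    if best_x is None:
        raise RuntimeError(f"all optimisation starts failed: {failures}")
    v, b, z, t0 = _unpack_theta(best_x, variant)
    params = LBAParameters(v=v, b=b, z=z, t0=t0, s=1.0)
    return params, -best_fun


def fit_cohort_bics(trials: pd.DataFrame, n_starts: int = 25,
                    n_presearch: int = 100, seed: int = 0,
                    variants=None) -> pd.DataFrame:
    """Fit every model variant to every subject and tabulate BIC.

    Returns a subjects x variants DataFrame of BIC values (the subject ids
    are the index, variant names the columns). ``-bic/2`` approximates the
    log model evidence consumed by the random-effects model selection.
    """
    if variants is None:
        variants = enumerate_variants()
    rows = {}
    for i, (sid, sub) in enumerate(trials.groupby("subject", sort=True)):
        sub = filter_trials(sub)
        rows[sid] = {
            var.name: bic(
                fit_lba(sub, var, n_starts=n_starts,
                        n_presearch=n_presearch, seed=seed + 1000 * i,
                        prefilter=False)[1],
                var.n_free_scalars, len(sub))
            for var in variants
        }
    return pd.DataFrame.from_dict(rows, orient="index")


class LBAModel(BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_lba`.

    Parameters
    ----------
    variant : str
        Name of the variant (e.g. ``"v"``, ``"v+t0"``): the parameters
        allowed to differ between the four condition cells.
    n_starts, n_presearch : int
        Multi-start optimisation schedule.
    seed : int
        Seed for the random pre-search.
    rt_window : tuple
        RT inclusion window in seconds; trials outside are omitted.

    Attributes
    ----------
    params_ : LBAParameters
    loglik_ : float
    bic_ : float
    n_trials_ : int
    """

    def __init__(self, variant="v", n_starts=25, n_presearch=100, seed=0,
                 rt_window=(0.1, 2.1)):
        self.variant = variant
        self.n_starts = n_starts
        self.n_presearch = n_presearch
        self.seed = seed
        self.rt_window = rt_window

    def fit(self, trials, y=None):
        var = ModelVariant(frozenset(self.variant.split("+")))
        if isinstance(trials, pd.DataFrame):
            trials = filter_trials(trials, rt_window=self.rt_window)
        self.variant_ = var
        self.params_, self.loglik_ = fit_lba(
            trials, var, n_starts=self.n_starts,
            n_presearch=self.n_presearch, seed=self.seed, prefilter=False)
        rt, _, _ = trials_to_arrays(trials)
        self.n_trials_ = int(rt.size)
        self.bic_ = bic(self.loglik_, var.n_free_scalars, self.n_trials_)
        return self

    def to_record(self) -> dict:
        return {
            "variant": self.variant_.name,
            "v": self.params_.v.tolist(), "b": self.params_.b.tolist(),
            "z": self.params_.z.tolist(), "t0": self.params_.t0.tolist(),
            "loglik": self.loglik_, "bic": self.bic_,
            "n_trials": self.n_trials_,
        }
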