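"""Cohort-level statistics: normal-mixture fitting and the model-based ROC.

A univariate K-component Gaussian mixture is fitted to the cohort's
signaling scores by EM (quantile-based initialisation plus random restarts,
best likelihood kept, SD floored to guard against degeneracy).  The number
of components is assessed by a parametric-bootstrap likelihood-ratio test —
the usual chi-square reference is invalid for mixtures.

The diagnostic cutoff is derived from the fitted model rather than from
empirical labels: with the components sorted by mean and the right-most
component taken as the disease-positive population,

    sens(c) = Phi((mu_pos - c) / sd_pos)
    FP(c)   = sum_{k != pos} w'_k * Phi((mu_k - c) / sd_k)

where the non-positive weights w'_k are renormalized to sum to one, i.e.
the false-positive rate is a probability conditional on belonging to the
non-positive sub-population.

Prevalence of combined-positive patients is reported with a Wilson score
interval by default.  A two-sample Kolmogorov-Smirnov comparison (with an
optional exact-permutation p-value) checks score distributions across
cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import ks_2samp, norm
from statsmodels.stats.proportion import proportion_confint

from .errors import DegeneracyError, InfeasibleCutoffError, ValidationError
from .synthetic_data import MixtureSpec

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureModel:
    """Fitted K-component univariate normal mixture, components sorted by mean."""

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    log_likelihood: float
    n: int
    converged: bool
    n_iter: int
    ll_history: tuple[float, ...] = ()

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValidationError("mixture weights must sum to 1 within 1e-12")
        if any(s <= 0 for s in self.sds):
            raise ValidationError("component SDs must be positive")
        if not np.isfinite(self.log_likelihood):
            raise ValidationError("log-likelihood must be finite")

    def to_spec(self) -> MixtureSpec:
        return MixtureSpec(self.weights, self.means, self.sds)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        labels = rng.choice(self.k, size=n, p=self.weights)
        return rng.normal(np.asarray(self.means)[labels],
                          np.asarray(self.sds)[labels])


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    false_positive_rate: float
    positive_component: int

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValidationError("sensitivity must be in [0, 1]")
        if not (0.0 <= self.false_positive_rate <= 1.0):
            raise ValidationError("false-positive rate must be in [0, 1]")


@dataclass(frozen=True)
class PrevalenceEstimate:
    n_pos: int
    n: int
    proportion: float
    ci_lower: float
    ci_upper: float
    ci_method: str
    level: float

    def __post_init__(self):
        if not (0.0 <= self.ci_lower <= self.proportion <= self.ci_upper <= 1.0):
            raise ValidationError("CI must bracket the proportion within [0, 1]")


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    p_value: float
    k0: int
    k1: int
    n_bootstrap: int
    n_redrawn: int


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    mode: str
    exact: bool = False


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _em_run(x, w, mu, sd, sd_floor, tol, max_iter):
    n = x.size
    ll_hist = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = (np.log(w)[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
                - np.log(sd)[None, :] - 0.5 * _LOG_2PI)
        row_ll = logsumexp(logp, axis=1)
        ll = float(row_ll.sum())
        ll_hist.append(ll)
        if np.isfinite(ll) and ll - ll_prev < tol * (abs(ll) + 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
        resp = np.exp(logp - row_ll[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
    if not converged:
        # refresh the likelihood for the final parameter update
        logp = (np.log(w)[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
                - np.log(sd)[None, :] - 0.5 * _LOG_2PI)
        ll_hist.append(float(logsumexp(logp, axis=1).sum()))
    return w, mu, sd, ll_hist[-1], tuple(ll_hist), converged, it


def fit_mixture_em(
    scores,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int | None = None,
    sd_floor_frac: float = 1e-3,
) -> MixtureModel:
    """Fit a K-component univariate normal mixture by EM.

    Initialisation: one quantile-based partition (K equal-count slices of
    the sorted data with the pooled SD) plus ``n_restarts - 1`` random
    initialisations; the best-likelihood solution is kept and components
    are returned in ascending-mean order.  Component SDs are floored at
    ``sd_floor_frac`` times the sample SD; a fit whose likelihood never
    becomes finite counts as degenerate, and if every restart degenerates a
    :class:`DegeneracyError` is raised.
    """
    x = np.asarray(scores, dtype=float).ravel()
    n = x.size
    if k < 1:
        raise ValidationError("K must be >= 1")
    if n <= 3 * k:
        raise ValidationError(f"need n > 3K data points (n={n}, K={k})")
    if not np.all(np.isfinite(x)):
        raise ValidationError("scores must be finite")
    sample_sd = float(np.std(x))
    if sample_sd == 0:
        raise DegeneracyError("all scores identical; mixture fit undefined")
    sd_floor = sd_floor_frac * sample_sd

    if k == 1:
        # EM reduces to the closed-form MLE
        mu = float(np.mean(x))
        sd = max(sample_sd, sd_floor)
        ll = float(np.sum(norm.logpdf(x, mu, sd)))
        return MixtureModel(1, (1.0,), (mu,), (sd,), ll, n, True, 1, (ll,))

    rng = np.random.default_rng(seed)
    xs = np.sort(x)
    inits = []
    # quantile partition init
    chunks = np.array_split(xs, k)
    inits.append((
        np.full(k, 1.0 / k),
        np.array([c.mean() for c in chunks]),
        np.full(k, max(sample_sd, sd_floor)),
    ))
    for _ in range(max(0, n_restarts - 1)):
        mu0 = rng.choice(x, size=k, replace=False)
        sd0 = np.full(k, max(sample_sd * rng.uniform(0.3, 1.0), sd_floor))
        inits.append((np.full(k, 1.0 / k), np.sort(mu0).astype(float), sd0))

    best = None
    for w0, mu0, sd0 in inits:
        w, mu, sd, ll, hist, conv, it = _em_run(
            x, w0.copy(), mu0.copy(), sd0.copy(), sd_floor, tol, max_iter)
        if not np.isfinite(ll):
            continue
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, hist, conv, it)
    if best is None:
        raise DegeneracyError("every EM restart degenerated")
    w, mu, sd, ll, hist, conv, it = best
    order = np.argsort(mu)
    w = w[order] / w[order].sum()
    return MixtureModel(
        k, tuple(float(v) for v in w), tuple(float(v) for v in mu[order]),
        tuple(float(v) for v in sd[order]), ll, n, bool(conv), it, hist,
    )


def mixture_log_likelihood(model: MixtureModel, x) -> float:
    x = np.asarray(x, float)
    logp = (np.log(model.weights)[None, :]
            - 0.5 * ((x[:, None] - np.asarray(model.means)[None, :])
                     / np.asarray(model.sds)[None, :]) ** 2
            - np.log(model.sds)[None, :] - 0.5 * _LOG_2PI)
    return float(logsumexp(logp, axis=1).sum())


# ---------------------------------------------------------------------------
# likelihood-ratio test by parametric bootstrap
# ---------------------------------------------------------------------------

def lrt_num_components(
    scores,
    k0: int,
    k1: int,
    n_bootstrap: int = 199,
    seed: int | None = None,
    max_redraws: int = 50,
    **fit_kwargs,
) -> LRTResult:
    """Parametric-bootstrap LRT of K0 versus K1 components.

    Simulates ``n_bootstrap`` datasets from the fitted K0 model, refits
    both models on each, and reports
    ``p = (1 + #{2*dLL* >= 2*dLL}) / (n_bootstrap + 1)``.  Refits that
    degenerate are re-drawn (counted in ``n_redrawn``).
    """
    if k1 <= k0:
        raise ValidationError("K1 must exceed K0")
    x = np.asarray(scores, float).ravel()
    rng = np.random.default_rng(seed)
    fit0 = fit_mixture_em(x, k0, seed=int(rng.integers(2**31)), **fit_kwargs)
    fit1 = fit_mixture_em(x, k1, seed=int(rng.integers(2**31)), **fit_kwargs)
    stat = max(0.0, 2.0 * (fit1.log_likelihood - fit0.log_likelihood))

    exceed = 0
    redrawn = 0
    for _ in range(n_bootstrap):
        for _attempt in range(max_redraws):
            xb = fit0.sample(x.size, rng)
            try:
                b0 = fit_mixture_em(xb, k0, seed=int(rng.integers(2**31)),
                                    **fit_kwargs)
                b1 = fit_mixture_em(xb, k1, seed=int(rng.integers(2**31)),
                                    **fit_kwargs)
            except DegeneracyError:
                redrawn += 1
                continue
            break
        else:
            raise DegeneracyError("bootstrap refits degenerated persistently")
        stat_b = max(0.0, 2.0 * (b1.log_likelihood - b0.log_likelihood))
        if stat_b >= stat:
            exceed += 1
    p = (1 + exceed) / (n_bootstrap + 1)
    return LRTResult(stat, p, k0, k1, n_bootstrap, redrawn)


# ---------------------------------------------------------------------------
# model-based ROC
# ---------------------------------------------------------------------------

def roc_from_mixture(
    model: MixtureModel,
    positive_component: int | None = None,
    cutoffs=None,
) -> list[CutoffResult]:
    """Sensitivity / false-positive pairs over a cutoff grid.

    The positive component defaults to the highest-mean (right-most)
    component.  Non-positive component weights are renormalized to sum to
    one, so FP is the probability that a patient drawn from the
    non-positive sub-population scores at or above the cutoff.
    """
    if model.k < 2:
        raise ValidationError("need at least 2 components for a model-based ROC")
    pos = model.k - 1 if positive_component is None else int(positive_component)
    if not (0 <= pos < model.k):
        raise ValidationError(f"positive component {pos} out of range 0..{model.k - 1}")
    mus = np.asarray(model.means)
    sds = np.asarray(model.sds)
    w = np.asarray(model.weights)
    neg = [i for i in range(model.k) if i != pos]
    w_neg = w[neg] / w[neg].sum()
    if cutoffs is None:
        lo = float(min(mus - 4 * sds))
        hi = float(max(mus + 4 * sds))
        cutoffs = np.linspace(lo, hi, 201)
    out = []
    for c in np.asarray(cutoffs, float):
        sens = float(norm.cdf((mus[pos] - c) / sds[pos]))
        fp = float(np.sum(w_neg * norm.cdf((mus[neg] - c) / sds[neg])))
        out.append(CutoffResult(float(c), sens, min(max(fp, 0.0), 1.0), pos))
    return out


def select_cutoff(roc: list[CutoffResult], max_fp: float) -> CutoffResult:
    """Smallest cutoff whose FP rate satisfies the bound.

    Because sensitivity and FP are both non-increasing in the cutoff, the
    smallest feasible cutoff maximizes sensitivity subject to FP <= max_fp.
    """
    if not roc:
        raise ValidationError("empty ROC grid")
    feasible = [r for r in roc if r.false_positive_rate <= max_fp]
    if not feasible:
        raise InfeasibleCutoffError(
            f"no cutoff on the grid achieves FP <= {max_fp}")
    return min(feasible, key=lambda r: r.cutoff)


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------

def prevalence(
    n_pos: int, n: int, method: str = "wilson", level: float = 0.95
) -> PrevalenceEstimate:
    """Binomial proportion with a Wilson (default) or Wald interval."""
    if n <= 0 or not (0 <= n_pos <= n):
        raise ValidationError("need 0 <= n_pos <= n with n > 0")
    sm_method = {"wilson": "wilson", "wald": "normal"}.get(method)
    if sm_method is None:
        raise ValidationError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(n_pos, n, alpha=1 - level, method=sm_method)
    prop = n_pos / n
    lo = min(max(float(lo), 0.0), prop)
    hi = max(min(float(hi), 1.0), prop)
    return PrevalenceEstimate(n_pos, n, prop, lo, hi, method, level)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov two-sample comparison
# ---------------------------------------------------------------------------

def _ks_stat(x: np.ndarray, y: np.ndarray) -> float:
    """sup |Fx - Fy| with right-continuous empirical CDFs (ties pooled)."""
    grid = np.concatenate([x, y])
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def ks_two_sample(
    x,
    y,
    mode: str = "asymptotic",
    n_permutations: int = 9999,
    seed: int | None = None,
    max_exact: int = 100_000,
) -> KSResult:
    """Two-sample KS test.

    ``asymptotic`` uses the Kolmogorov limiting distribution; ``permutation``
    reassigns the pooled sample to the two groups — exhaustively when the
    number of distinct splits is at most ``max_exact`` (p is then the exact
    proportion of splits, including the observed one, with D* >= D), and by
    ``n_permutations`` random splits otherwise with the add-one correction
    ``p = (1 + #{D* >= D}) / (n_permutations + 1)``.  Tied values are
    handled by the pooled right-continuous step-function convention.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValidationError("both samples need n >= 2")
    d = _ks_stat(x, y)
    if mode == "asymptotic":
        res = ks_2samp(x, y, method="asymp")
        return KSResult(d, float(res.pvalue), mode)
    if mode != "permutation":
        raise ValidationError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    n1, ntot = x.size, pooled.size
    n_splits = math.comb(ntot, n1)
    tol = 1e-12
    if n_splits <= max_exact:
        count = 0
        idx_all = frozenset(range(ntot))
        for comb in itertools.combinations(range(ntot), n1):
            xa = pooled[list(comb)]
            ya = pooled[list(idx_all - set(comb))]
            if _ks_stat(xa, ya) >= d - tol:
                count += 1
        return KSResult(d, count / n_splits, mode, exact=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _ks_stat(perm[:n1], perm[n1:]) >= d - tol:
            count += 1
    return KSResult(d, (1 + count) / (n_permutations + 1), mode, exact=False)
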