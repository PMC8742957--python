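"""Dose-response analysis: fraction affected, median-effect and 4PL fits.

Signaling scores from drug/agonist titrations are first normalized to a
fraction affected ``fa`` in (0, 1): for agonists the fraction of the
maximal agonist response achieved, for inhibitors the fraction of the
reference signal suppressed.  Values are clipped away from 0/1 before the
logit-type median-effect transform (which diverges at the bounds); every
clip is logged.

Two models are fitted:

* **median-effect**: ``fa/fu = (d/Dm)^m`` — a straight line of slope ``m``
  and intercept ``-m log10(Dm)`` in log10(fa/fu) versus log10(d);
* **four-parameter logistic**: ``floor + (ceiling-floor)/(1 + (d/Dm)^{-+m})``
  by bounded nonlinear least squares, initialized from the median-effect
  line.

``Dm`` is the dose of half-maximal effect (IC50 for inhibitors, EC50 for
agonists; for the 4PL it is the inflection, i.e. a relative IC50).  The
inhibitor/agonist orientation is always an explicit flag, never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress
from scipy.stats import t as t_dist

from .errors import (
    FitError,
    InformationError,
    OrientationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MODES = ("inhibitor", "agonist")


@dataclass(frozen=True)
class FractionAffected:
    """Normalized effect level at one dose, with clipping provenance."""

    dose_molar: float | None
    fa: float
    clipped: bool
    raw_fraction: float
    mode: str

    @property
    def fu(self) -> float:
        return 1.0 - self.fa


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted potency parameters.

    ``dm`` (molar) is the half-effect dose, ``m`` the slope.  ``floor`` and
    ``ceiling`` are populated for the 4PL only.  ``dm_ci`` is a 95%
    confidence interval on ``dm`` (from the log10-scale standard error)
    when available.
    """

    model: str
    dm: float
    m: float
    mode: str
    n_points: int
    dose_range: tuple[float, float]
    residual_se: float
    r_squared: float | None = None
    floor: float | None = None
    ceiling: float | None = None
    dm_ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.dm <= 0 or self.m <= 0:
            raise ValidationError("fitted Dm and m must be positive")

    def fraction_at(self, dose) -> np.ndarray | float:
        """Median-effect fraction affected at the given dose(s)."""
        d = np.asarray(dose, float)
        r = (d / self.dm) ** self.m
        out = r / (1.0 + r)
        return float(out) if np.isscalar(dose) else out


def fraction_affected(
    score_treated: float,
    score_reference_max: float,
    score_baseline: float,
    mode: str = "inhibitor",
    epsilon: float = 0.01,
    dose_molar: float | None = None,
) -> FractionAffected:
    """Normalize a treated-well score to a fraction affected in (0, 1).

    ``raw = (treated - baseline) / (reference - baseline)`` is the percent-
    of-maximum response; ``fa = 1 - raw`` (fraction inhibited) for
    inhibitors and ``fa = raw`` (fraction activated) for agonists, clipped
    to ``[epsilon, 1 - epsilon]``.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if not (0 < epsilon < 0.1):
        raise ValidationError("epsilon must be in (0, 0.1)")
    if score_reference_max <= score_baseline:
        raise ValidationError("reference-max score must exceed the baseline")
    raw = (score_treated - score_baseline) / (score_reference_max - score_baseline)
    fa = (1.0 - raw) if mode == "inhibitor" else raw
    clipped = not (epsilon <= fa <= 1.0 - epsilon)
    if clipped:
        logger.info("fraction_affected clipped: fa=%.4g -> [%g, %g]",
                    fa, epsilon, 1 - epsilon)
    return FractionAffected(
        dose_molar, float(np.clip(fa, epsilon, 1.0 - epsilon)),
        clipped, float(raw), mode,
    )


def titration_doses(
    top_dose: float, n_points: int = 5, span_fold: float = 1000.0
) -> np.ndarray:
    """Geometric titration from ``top/span_fold`` up to ``top`` (ascending).

    The default is the five-point 1000-fold design (dilution factor
    1000^(1/4), roughly 5.62 between adjacent doses).
    """
    if top_dose <= 0 or n_points < 2 or span_fold <= 1:
        raise ValidationError("invalid titration design")
    return top_dose * span_fold ** (np.linspace(-1.0, 0.0, n_points))


def fit_median_effect(
    doses: Sequence[float],
    fa: Sequence[float],
    mode: str = "inhibitor",
) -> DoseResponseFit:
    """Least-squares median-effect line on log10(fa/fu) versus log10(dose)."""
    d = np.asarray(doses, float)
    f = np.asarray(fa, float)
    if d.size != f.size or d.size < 2:
        raise ValidationError("need >= 2 matched (dose, fa) points")
    if np.any(d <= 0):
        raise ValidationError("doses must be positive")
    if np.any((f <= 0) | (f >= 1)):
        raise ValidationError("fa values must lie strictly in (0, 1)")
    if np.unique(d).size < 2:
        raise ValidationError("need at least 2 distinct doses")
    if np.unique(f).size == 1:
        raise InformationError(
            "all fa values identical (fully clipped titration carries no "
            "dose-response information)")
    logd = np.log10(d)
    logit = np.log10(f / (1.0 - f))
    res = linregress(logd, logit)
    m = float(res.slope)
    if m <= 0:
        raise OrientationError(
            "median-effect slope is non-positive; check the fa orientation")
    dm = float(10.0 ** (-res.intercept / m))
    pred = res.intercept + m * logd
    dof = max(d.size - 2, 1)
    rse = float(np.sqrt(np.sum((logit - pred) ** 2) / dof))
    dm_ci = None
    if d.size > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        # delta-method interval on log10(Dm) = -intercept/slope
        se_log_dm = np.sqrt(
            (res.intercept_stderr / m) ** 2
            + (res.intercept * res.stderr / m**2) ** 2)
        q = t_dist.ppf(0.975, d.size - 2)
        dm_ci = (float(dm * 10 ** (-q * se_log_dm)),
                 float(dm * 10 ** (q * se_log_dm)))
    return DoseResponseFit(
        model="median_effect", dm=dm, m=m, mode=mode, n_points=int(d.size),
        dose_range=(float(d.min()), float(d.max())), residual_se=rse,
        r_squared=float(res.rvalue**2), dm_ci=dm_ci,
    )


def _four_pl(logd, floor, ceiling, log_dm, m, sign):
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (sign * m * (log_dm - logd)))


def fit_four_pl(
    doses: Sequence[float],
    responses: Sequence[float],
    mode: str = "inhibitor",
    epsilon: float = 0.01,
) -> DoseResponseFit:
    """Four-parameter logistic fit by bounded nonlinear least squares.

    For agonists the response rises from floor to ceiling with dose; for
    inhibitors it falls from ceiling to floor.  Data that are strictly
    monotone against the declared direction raise an
    :class:`OrientationError`.  Initial values come from a median-effect
    line on the range-normalized responses.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    d = np.asarray(doses, float)
    r = np.asarray(responses, float)
    if d.size != r.size or d.size < 4:
        raise ValidationError("need >= 4 matched (dose, response) points")
    if np.any(d <= 0):
        raise ValidationError("doses must be positive")
    if np.log10(d.max() / d.min()) < 2.0:
        raise ValidationError("doses must span at least 2 log10 units")
    order = np.argsort(d)
    diffs = np.diff(r[order])
    if mode == "inhibitor" and np.all(diffs > 0):
        raise OrientationError("response rises with dose but flag says inhibitor")
    if mode == "agonist" and np.all(diffs < 0):
        raise OrientationError("response falls with dose but flag says agonist")

    lo, hi = float(r.min()), float(r.max())
    span = max(hi - lo, 1e-12)
    frac = np.clip((r - lo) / span, epsilon, 1 - epsilon)
    fa0 = (1.0 - frac) if mode == "inhibitor" else frac
    try:
        me = fit_median_effect(d, fa0, mode=mode)
        log_dm0, m0 = np.log10(me.dm), min(me.m, 10.0)
    except (ValidationError, OrientationError, InformationError):
        log_dm0, m0 = float(np.median(np.log10(d))), 1.0

    sign = 1.0 if mode == "agonist" else -1.0
    logd = np.log10(d)
    p0 = [lo, hi, log_dm0, m0]
    bounds = (
        [lo - 2 * span, lo - 2 * span, np.log10(d.min()) - 3, 1e-3],
        [hi + 2 * span, hi + 2 * span, np.log10(d.max()) + 3, 50.0],
    )
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        popt, pcov = curve_fit(
            lambda ld, fl, ce, ldm, mm: _four_pl(ld, fl, ce, ldm, mm, sign),
            logd, r, p0=p0, bounds=bounds, maxfev=20_000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL regression failed to converge: {exc}") from exc
    floor_, ceiling_, log_dm, m = (float(v) for v in popt)
    pred = _four_pl(logd, floor_, ceiling_, log_dm, m, sign)
    dof = max(d.size - 4, 1)
    rse = float(np.sqrt(np.sum((r - pred) ** 2) / dof))
    dm = 10.0 ** log_dm
    dm_ci = None
    se_log_dm = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.nan
    if np.isfinite(se_log_dm):
        # t-quantile: residual degrees of freedom are tiny in 5-point designs
        q = t_dist.ppf(0.975, dof)
        dm_ci = (float(dm * 10 ** (-q * se_log_dm)),
                 float(dm * 10 ** (q * se_log_dm)))
    return DoseResponseFit(
        model="four_pl", dm=float(dm), m=float(m), mode=mode,
        n_points=int(d.size), dose_range=(float(d.min()), float(d.max())),
        residual_se=rse, floor=floor_, ceiling=ceiling_, dm_ci=dm_ci,
    )


def ecx(fit: DoseResponseFit, x: float) -> float:
    """Dose producing effect level ``x``: ``Dm * (x/(1-x))^(1/m)``."""
    if not (0.0 < x < 1.0):
        raise ValidationError("effect level x must be in (0, 1)")
    return float(fit.dm * (x / (1.0 - x)) ** (1.0 / fit.m))


@dataclass(frozen=True)
class PotencySummary:
    drug: str
    mean_ic50: float
    n: int
    values: tuple[float, ...]


def summarize_potency(fits: Sequence[DoseResponseFit], drug: str) -> PotencySummary:
    """Arithmetic mean of per-patient IC50/EC50 values."""
    if not fits:
        raise ValidationError("need at least one fit")
    vals = tuple(f.dm for f in fits)
    return PotencySummary(drug, float(np.mean(vals)), len(vals), vals)
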