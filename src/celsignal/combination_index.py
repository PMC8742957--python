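"""Chou-Talalay combination-index analysis for constant-ratio designs.

At a shared effect level ``fa``, the combination index of a dose pair
``(d1, d2)`` is

    CI = d1/Dx1(fa) + d2/Dx2(fa)                    (mutually exclusive)
    CI = ... + (d1 d2)/(Dx1 Dx2)                    (non-exclusive)

where ``Dx_i(fa) = Dm_i (fa/(1-fa))^(1/m_i)`` is the dose of agent ``i``
alone that produces ``fa``, from that agent's own median-effect fit.
CI < 1 indicates synergy, CI = 1 additivity (Loewe), CI > 1 antagonism.
The mutually exclusive two-term form is the default, matching agents whose
effects compete for the same effector pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import DoseResponseFit
from .errors import ValidationError

logger = logging.getLogger(__name__)

CI_FORMS = ("mutually_exclusive", "non_exclusive")


@dataclass(frozen=True)
class CombinationPoint:
    """One constant-ratio escalation level with its combination index."""

    d1: float
    d2: float
    fa: float
    dx1: float
    dx2: float
    ci: float
    n_replicates: int = 1

    def __post_init__(self):
        if self.ci <= 0:
            raise ValidationError("combination index must be positive")


@dataclass(frozen=True)
class RatioDesign:
    """Fixed-ratio dose escalation: d2 = ratio * d1 at every level."""

    ratio: float
    levels: tuple[tuple[float, float], ...]
    rationale: str = ""

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValidationError("ratio must be positive")
        lv = tuple((float(a), float(b)) for a, b in self.levels)
        if not lv:
            raise ValidationError("design needs at least one level")
        d1s = [a for a, _ in lv]
        if any(a <= 0 or b <= 0 for a, b in lv):
            raise ValidationError("dose levels must be positive")
        if not all(x < y for x, y in zip(d1s, d1s[1:])):
            raise ValidationError("dose levels must be strictly increasing")
        for a, b in lv:
            if abs(b / a - self.ratio) > 1e-6 * self.ratio:
                raise ValidationError(
                    f"level ({a}, {b}) violates the fixed ratio {self.ratio}")
        object.__setattr__(self, "levels", lv)

    @classmethod
    def from_d1_levels(cls, d1_levels: Sequence[float], ratio: float,
                       rationale: str = "") -> "RatioDesign":
        return cls(ratio, tuple((float(d), float(d) * ratio) for d in d1_levels),
                   rationale)


def dose_for_effect(fit: DoseResponseFit, fa: float) -> float:
    """Single-agent dose producing effect ``fa``: the median-effect inverse."""
    if not (0.0 < fa < 1.0):
        raise ValidationError("fa must be in (0, 1)")
    if fa <= 0.01 or fa >= 0.99:
        logger.warning("dose_for_effect at fa=%.4g (clip-bound region): "
                       "the extrapolated Dx is unreliable", fa)
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def combination_index(
    d1: float,
    d2: float,
    fit1: DoseResponseFit,
    fit2: DoseResponseFit,
    fa_combo: float,
    form: str = "mutually_exclusive",
) -> float:
    """Combination index of the dose pair at the observed combined effect."""
    if form not in CI_FORMS:
        raise ValidationError(f"form must be one of {CI_FORMS}")
    if not (0.0 < fa_combo < 1.0):
        raise ValidationError("fa_combo must be in (0, 1)")
    if d1 < 0 or d2 < 0:
        raise ValidationError("doses must be non-negative")
    dx1 = dose_for_effect(fit1, fa_combo)
    dx2 = dose_for_effect(fit2, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    if form == "non_exclusive":
        ci += (d1 * d2) / (dx1 * dx2)
    return float(ci)


def constant_ratio_series(
    design: RatioDesign,
    fit1: DoseResponseFit,
    fit2: DoseResponseFit,
    fa_observed: Sequence[float | Sequence[float]],
    form: str = "mutually_exclusive",
) -> list[CombinationPoint]:
    """Combination index at every escalation level of a fixed-ratio design.

    ``fa_observed[i]`` is the combined-exposure fraction affected at level
    ``i`` — a scalar or a sequence of replicate values, which are averaged
    before the CI computation (the replicate count is recorded).  A
    non-monotone fa sequence is flagged with a warning, not an error.
    """
    if len(fa_observed) != len(design.levels):
        raise ValidationError(
            f"{len(design.levels)} design levels but {len(fa_observed)} fa values")
    fa_means, ns = [], []
    for fa in fa_observed:
        arr = np.atleast_1d(np.asarray(fa, float))
        fa_means.append(float(arr.mean()))
        ns.append(int(arr.size))
    if np.any(np.diff(fa_means) < 0):
        logger.warning("fraction affected is non-monotone across dose levels")
    points = []
    for (d1, d2), fa, n in zip(design.levels, fa_means, ns):
        dx1 = dose_for_effect(fit1, fa)
        dx2 = dose_for_effect(fit2, fa)
        ci = combination_index(d1, d2, fit1, fit2, fa, form)
        points.append(CombinationPoint(d1, d2, fa, dx1, dx2, ci, n))
    return points


def classify_interaction(
    ci: float, lower: float = 0.9, upper: float = 1.1
) -> str:
    """Label a CI as synergy (< lower), antagonism (> upper) or additive.

    The dead band around 1 avoids noise-driven flips; set
    ``lower = upper = 1`` for the bare <1/>1 reading.
    """
    if ci <= 0:
        raise ValidationError("CI must be positive")
    if lower > upper:
        raise ValidationError("lower threshold exceeds upper threshold")
    if ci < lower:
        return "synergy"
    if ci > upper:
        return "antagonism"
    return "additive"


def series_to_frame(points: Sequence[CombinationPoint]) -> pd.DataFrame:
    """Tabular view of a combination series (doses, fa %, CI, class)."""
    return pd.DataFrame([
        {
            "dose1_molar": p.d1, "dose2_molar": p.d2,
            "fraction_affected_pct": 100.0 * p.fa,
            "combination_index": p.ci,
            "interaction": classify_interaction(p.ci),
            "n_replicates": p.n_replicates,
        }
        for p in points
    ])
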