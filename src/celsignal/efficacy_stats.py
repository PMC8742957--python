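"""Percent inhibition, cross-talk matrices, cocktail summaries, xenograft stats.

Percent inhibition of an agonist-evoked signal by a drug is

    100 * (1 - (S_drug - S_baseline) / (S_agonist - S_baseline))

so 0% means the drug left the signal untouched, 100% a complete block back
to baseline, values above 100% suppression below baseline, and *negative*
values an enhanced response under drug — the signature of feedback release
when an unmatched receptor is inhibited.

The cross-talk matrix evaluates this quantity for every (agonist drug)
pair of a panel; on-target cells sit on the matched diagonal.  Xenograft
efficacy is summarized as percent tumor reduction at the endpoint day,
``100 * (1 - mean(V_treated) / mean(V_control))``, with a Welch two-sample
t-test on the endpoint volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .errors import CompletenessError, ValidationError


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Percent-inhibition entries (rows: agonists; columns: antagonists)."""

    patient_id: str
    values: pd.DataFrame   # float entries, may be negative
    counts: pd.DataFrame   # replicate counts per cell, all >= 1

    def __post_init__(self):
        if self.values.shape != self.counts.shape:
            raise ValidationError("values and counts shapes differ")
        if (self.counts.to_numpy() < 1).any():
            raise ValidationError("every cell needs n >= 1 replicates")


@dataclass(frozen=True)
class XenograftSummary:
    arm: str
    comparator: str
    endpoint_day: float
    n_treated: int
    n_control: int
    mean_volume_treated: float
    mean_volume_control: float
    percent_reduction: float
    t_statistic: float
    p_value: float
    test: str


def percent_inhibition(
    score_drug: float, score_agonist: float, score_baseline: float
) -> float:
    """Percent inhibition of the agonist signal; negative = enhancement."""
    if score_agonist <= score_baseline:
        raise ValidationError(
            "agonist signal must exceed baseline (undefined denominator)")
    return 100.0 * (1.0 - (score_drug - score_baseline)
                    / (score_agonist - score_baseline))


def crosstalk_matrix(
    scores: pd.DataFrame,
    agonists: Sequence[str],
    antagonists: Sequence[str],
    patient_id: str = "",
) -> CrosstalkMatrix:
    """Build the agonist x antagonist percent-inhibition grid for one patient.

    ``scores`` is tidy with columns ``agonist`` (empty/NaN for the
    no-agonist baseline), ``antagonist`` (empty/NaN for agonist-only
    reference wells) and ``score``; replicate rows are averaged.  Every
    (agonist, antagonist) cell, every agonist-only reference and the
    baseline must be present, otherwise a :class:`CompletenessError` lists
    what is missing.
    """
    df = scores.copy()
    for col in ("agonist", "antagonist"):
        if col not in df.columns:
            raise ValidationError(f"scores table needs an {col!r} column")
        df[col] = df[col].fillna("").astype(str)
    base = df[(df["agonist"] == "") & (df["antagonist"] == "")]["score"]
    missing: list[str] = []
    if base.empty:
        missing.append("baseline (no agonist, no drug)")
    refs = {}
    for ag in agonists:
        ref = df[(df["agonist"] == ag) & (df["antagonist"] == "")]["score"]
        if ref.empty:
            missing.append(f"agonist-only reference for {ag}")
        else:
            refs[ag] = float(ref.mean())
    cells = {}
    for ag in agonists:
        for drug in antagonists:
            cell = df[(df["agonist"] == ag) & (df["antagonist"] == drug)]["score"]
            if cell.empty:
                missing.append(f"({ag}, {drug}) well")
            else:
                cells[(ag, drug)] = (float(cell.mean()), int(cell.size))
    if missing:
        raise CompletenessError("missing wells: " + "; ".join(missing))
    b = float(base.mean())
    values = pd.DataFrame(index=list(agonists), columns=list(antagonists),
                          dtype=float)
    counts = pd.DataFrame(index=list(agonists), columns=list(antagonists),
                          dtype=int)
    for (ag, drug), (mean_score, n) in cells.items():
        values.loc[ag, drug] = percent_inhibition(mean_score, refs[ag], b)
        counts.loc[ag, drug] = n
    return CrosstalkMatrix(patient_id, values, counts)


def cocktail_inhibition(
    scores_drug: Sequence[float],
    scores_cocktail_ref: Sequence[float],
    scores_baseline: Sequence[float],
) -> tuple[float, float, int]:
    """Percent inhibition of the combined-agonist (cocktail) signal.

    Per-replicate drug-well inhibitions are computed against the mean
    cocktail reference and mean baseline; returns (mean %, SD, n).
    """
    drug = np.asarray(list(scores_drug), float)
    if drug.size == 0:
        raise ValidationError("need at least one drug-well score")
    ref = float(np.mean(np.asarray(list(scores_cocktail_ref), float)))
    base = float(np.mean(np.asarray(list(scores_baseline), float)))
    vals = np.array([percent_inhibition(s, ref, base) for s in drug])
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def tumor_reduction(
    volumes_treated: Sequence[float],
    volumes_control: Sequence[float],
    arm: str = "treated",
    comparator: str = "control",
    endpoint_day: float = 21.0,
    test: str = "welch",
) -> XenograftSummary:
    """Percent tumor reduction at endpoint with a two-sample t-test.

    ``welch`` (default) uses unequal variances; ``student`` pools them.
    """
    vt = np.asarray(list(volumes_treated), float)
    vc = np.asarray(list(volumes_control), float)
    if vt.size < 2 or vc.size < 2:
        raise ValidationError("both arms need >= 2 mice")
    if np.any(vt <= 0) or np.any(vc <= 0):
        raise ValidationError("tumor volumes must be positive")
    if test not in ("welch", "student"):
        raise ValidationError(f"unknown test {test!r}")
    reduction = 100.0 * (1.0 - vt.mean() / vc.mean())
    res = ttest_ind(vt, vc, equal_var=(test == "student"))
    return XenograftSummary(
        arm=arm, comparator=comparator, endpoint_day=endpoint_day,
        n_treated=int(vt.size), n_control=int(vc.size),
        mean_volume_treated=float(vt.mean()),
        mean_volume_control=float(vc.mean()),
        percent_reduction=float(reduction),
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        test=test,
    )


def endpoint_volumes(
    volumes: pd.DataFrame,
    arm: str,
    endpoint_day: float,
    exclude: Sequence[str] = (),
) -> np.ndarray:
    """Endpoint-day volumes of one arm, honoring an explicit exclusion list."""
    df = volumes[(volumes["arm"] == arm) & (volumes["day"] == endpoint_day)]
    df = df[~df["mouse_id"].isin(set(exclude))]
    if df.empty:
        raise ValidationError(f"no volumes for arm {arm!r} at day {endpoint_day}")
    return df["volume_mm3"].to_numpy(dtype=float)
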