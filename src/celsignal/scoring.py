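"""Pathway signaling scores from paired treated/control impedance traces.

The test score is the sum of per-minute Cell Index differences between a
treated well and the matched control well over a 240-minute window after
agonist addition:

    S = sum_{i=0}^{240} (T_i - C_i)

The summation bounds are inclusive (241 terms).  Traces recorded on any
grid are linearly interpolated onto the 1-minute grid first; the sole
normalization is the control-well subtraction.

HER-family decomposition from the five-well scheme (C, CF1, CDF1, CF2,
CDF2): the HER2 score is the dimer contribution lost when the blocking
antibody is present, summed over both ligand arms,
``sum(CF1-CDF1) + sum(CF2-CDF2)``; the residual blocked-well responses
attribute ``sum(CDF1-C)`` to HER3/4 and ``sum(CDF2-C)`` to HER1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, CoverageError, ValidationError
from .plate_io import PATHWAYS, ImpedanceTrace, PlateLayout

DEFAULT_WINDOW_MIN = 240


@dataclass(frozen=True)
class SignalingScore:
    """Replicate-aggregated score for one patient x pathway."""

    patient_id: str
    pathway: str
    score: float
    n_replicates: int
    replicate_sd: float  # 0.0 (flagged by n_replicates == 1) when undefined

    def __post_init__(self):
        if not np.isfinite(self.score):
            raise ValidationError("score must be finite")
        if self.n_replicates < 1:
            raise ValidationError("need at least one replicate")


@dataclass(frozen=True)
class PatientCall:
    """Per-pathway positivity and the combined co-activation flag.

    ``combined`` is true iff the c-Met pathway is positive and at least one
    HER-family pathway is positive.
    """

    patient_id: str
    positive: Mapping[str, bool]
    combined: bool

    def __post_init__(self):
        object.__setattr__(self, "positive", dict(self.positive))
        her = any(self.positive.get(p, False) for p in ("HER1", "HER2", "HER3_4"))
        expected = bool(self.positive.get("cMet", False) and her)
        if self.combined != expected:
            raise ValidationError("combined flag inconsistent with pathway flags")


def resample_to_minutes(trace: ImpedanceTrace, window_min: int = DEFAULT_WINDOW_MIN
                        ) -> np.ndarray:
    """Linearly interpolate a trace onto the inclusive 0..window 1-min grid."""
    if trace.times[0] > 0 or trace.times[-1] < window_min:
        raise CoverageError(
            f"well {trace.well_id}: trace [{trace.times[0]}, {trace.times[-1]}] "
            f"does not cover [0, {window_min}] min"
        )
    grid = np.arange(window_min + 1, dtype=float)
    return np.interp(grid, trace.times, trace.cell_index)


def signaling_score(
    treated: ImpedanceTrace,
    control: ImpedanceTrace,
    window_min: int = DEFAULT_WINDOW_MIN,
) -> float:
    """Summed per-minute treated-minus-control difference (signaling units)."""
    t = resample_to_minutes(treated, window_min)
    c = resample_to_minutes(control, window_min)
    return float(np.sum(t - c))


def her_family_scores(
    cf1: ImpedanceTrace,
    cdf1: ImpedanceTrace,
    cf2: ImpedanceTrace,
    cdf2: ImpedanceTrace,
    c: ImpedanceTrace,
    window_min: int = DEFAULT_WINDOW_MIN,
) -> dict[str, float]:
    """Decompose the five-well HER scheme into HER1, HER2 and HER3/4 scores."""
    return {
        "HER2": (signaling_score(cf1, cdf1, window_min)
                 + signaling_score(cf2, cdf2, window_min)),
        "HER3_4": signaling_score(cdf1, c, window_min),
        "HER1": signaling_score(cdf2, c, window_min),
    }


def aggregate_replicates(
    replicate_scores: Sequence[float], patient_id: str, pathway: str
) -> SignalingScore:
    """Mean score across replicate wells with the between-replicate SD."""
    vals = np.asarray(list(replicate_scores), dtype=float)
    if vals.size == 0:
        raise ValidationError("need at least one replicate score")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SignalingScore(
        patient_id=patient_id, pathway=pathway, score=float(np.mean(vals)),
        n_replicates=int(vals.size), replicate_sd=sd,
    )


def classify_patient(
    patient_id: str,
    scores: Mapping[str, float],
    cutoffs: Mapping[str, float],
) -> PatientCall:
    """Flag each pathway as positive iff its score >= its cutoff.

    A missing c-Met score is an error; missing HER pathways are treated as
    negative (they simply cannot contribute a co-activation).
    """
    if "cMet" not in scores:
        raise ValidationError(f"patient {patient_id}: missing cMet score")
    for p, cut in cutoffs.items():
        if not np.isfinite(cut):
            raise ValidationError(f"non-finite cutoff for {p}")
    positive = {
        p: bool(scores[p] >= cutoffs.get(p, np.inf)) for p in scores if p in PATHWAYS
    }
    her = any(positive.get(p, False) for p in ("HER1", "HER2", "HER3_4"))
    return PatientCall(patient_id, positive, bool(positive["cMet"] and her))


def classify_cohort(
    score_table: pd.DataFrame, cutoffs: Mapping[str, float]
) -> list[PatientCall]:
    """Classify every patient of a cohort score table."""
    calls = []
    for pid, grp in score_table.groupby("patient_id", sort=True):
        scores = dict(zip(grp["pathway"], grp["score"]))
        calls.append(classify_patient(str(pid), scores, cutoffs))
    return calls


def score_plate(
    traces: Sequence[ImpedanceTrace],
    layout: PlateLayout,
    window_min: int = DEFAULT_WINDOW_MIN,
) -> tuple[pd.DataFrame, list[SignalingScore]]:
    """Compute all four pathway scores for every patient on a plate.

    The control reference for each patient is the mean resampled C-well
    vector (averaging control replicates before subtraction).  Treated
    conditions are scored per replicate against that reference and then
    replicate-aggregated; the HER decomposition likewise uses per-condition
    mean vectors for the paired CF/CDF differences, with the replicate SD
    reported from the per-replicate single-difference scores.

    Returns the tidy cohort score table and the full aggregate records.
    """
    by_id = {tr.well_id: tr for tr in traces}
    resampled: dict[str, np.ndarray] = {}

    def vec(well_id: str) -> np.ndarray:
        if well_id not in resampled:
            resampled[well_id] = resample_to_minutes(by_id[well_id], window_min)
        return resampled[well_id]

    def condition_vectors(pid: str, code: str) -> dict[int, np.ndarray]:
        wells = {
            w: c for w, c in layout.wells_for(pid, code).items() if w in by_id
        }
        return {c.replicate: vec(w) for w, c in wells.items()}

    records: list[SignalingScore] = []
    for pid in layout.patients():
        c_vecs = condition_vectors(pid, "C")
        if not c_vecs:
            raise CompletenessError(f"patient {pid}: no control (C) well traced")
        c_mean = np.mean(list(c_vecs.values()), axis=0)

        cond = {code: condition_vectors(pid, code)
                for code in ("CF1", "CDF1", "CF2", "CDF2", "CF3")}
        missing = [code for code, vv in cond.items() if not vv]
        if missing:
            raise CompletenessError(f"patient {pid}: missing wells for {missing}")
        mean_of = {code: np.mean(list(vv.values()), axis=0)
                   for code, vv in cond.items()}

        # c-Met: per-replicate CF3 scores against the mean control
        cmet_reps = [float(np.sum(v - c_mean)) for _, v in sorted(cond["CF3"].items())]
        records.append(aggregate_replicates(cmet_reps, pid, "cMet"))

        # HER family from condition-mean vectors
        her2 = float(np.sum(mean_of["CF1"] - mean_of["CDF1"])
                     + np.sum(mean_of["CF2"] - mean_of["CDF2"]))
        her34_reps = [float(np.sum(v - c_mean)) for _, v in sorted(cond["CDF1"].items())]
        her1_reps = [float(np.sum(v - c_mean)) for _, v in sorted(cond["CDF2"].items())]
        n_her2 = min(len(cond["CF1"]), len(cond["CDF1"]),
                     len(cond["CF2"]), len(cond["CDF2"]))
        records.append(SignalingScore(pid, "HER2", her2, n_her2, 0.0))
        records.append(aggregate_replicates(her34_reps, pid, "HER3_4"))
        records.append(aggregate_replicates(her1_reps, pid, "HER1"))

    table = pd.DataFrame(
        [{"patient_id": r.patient_id, "pathway": r.pathway, "score": r.score}
         for r in records]
    ).sort_values(["patient_id", "pathway"]).reset_index(drop=True)
    return table, records
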