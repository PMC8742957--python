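"""Reading and writing the tabular artifacts of the signaling pipeline.

All tables are plain comma-separated UTF-8 text with a mandatory header row
and "." as the decimal mark.  Five kinds are handled:

* plate traces   — ``time_min`` column plus one Cell Index column per well;
* plate layouts  — structured YAML mapping wells to experimental conditions;
* cohort scores  — ``patient_id,pathway,score`` (signaling units);
* dose-response  — ``drug,agonist,dose_molar,response``;
* xenograft      — ``mouse_id,arm,day,volume_mm3``.

Time is expressed in minutes relative to agonist addition (minute 0); rows
with negative times are a pre-addition baseline and are retained on read but
ignored by the scorer.  Readers validate and raise rather than silently
dropping rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Pathways reported by the multi-pathway test.
PATHWAYS = ("cMet", "HER1", "HER2", "HER3_4")

#: Well condition codes and the agonist each implies.  C wells receive
#: control medium only; CF wells receive a single pathway factor; CDF wells
#: additionally contain the HER2 dimerization-blocking antibody.  DRUG is a
#: free-form code for titration / combination wells.
CONDITION_AGONIST: Mapping[str, str | None] = {
    "C": None,
    "CF1": "NRG1b",
    "CDF1": "NRG1b",
    "CF2": "EGF",
    "CDF2": "EGF",
    "CF3": "HGF",
}

AGONISTS = ("NRG1b", "EGF", "HGF", "cocktail")

#: Default agonist doses (molar): 3 nM NRG1b, 0.3 nM EGF, 0.08 nM HGF,
#: each approximately the EC90 of its pathway.
DEFAULT_AGONIST_DOSE_M: Mapping[str, float] = {
    "NRG1b": 3e-9,
    "EGF": 3e-10,
    "HGF": 8e-11,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpedanceTrace:
    """One well's Cell Index time series.

    ``times`` are minutes since agonist addition (strictly increasing, may
    start below zero for baseline samples); ``cell_index`` is the
    dimensionless impedance readout, one value per time point.
    """

    well_id: str
    times: np.ndarray
    cell_index: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        ci = np.asarray(self.cell_index, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cell_index", ci)
        if t.ndim != 1 or ci.ndim != 1:
            raise ValidationError(f"well {self.well_id}: times/cell_index must be 1-D")
        if t.size != ci.size:
            raise ValidationError(
                f"well {self.well_id}: times ({t.size}) and cell_index "
                f"({ci.size}) lengths differ"
            )
        if t.size < 2:
            raise ValidationError(f"well {self.well_id}: needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValidationError(f"well {self.well_id}: times not strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(ci))):
            raise ValidationError(f"well {self.well_id}: non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Antagonist:
    drug: str
    dose_molar: float

    def __post_init__(self):
        if self.dose_molar < 0:
            raise ValidationError(f"antagonist {self.drug}: negative dose")


@dataclass(frozen=True)
class WellCondition:
    """Experimental condition of one well."""

    condition_code: str
    patient_id: str
    replicate: int = 1
    agonist: str | None = None
    agonist_dose_molar: float | None = None
    antagonists: tuple[Antagonist, ...] = ()
    her2_blocked: bool = False

    def __post_init__(self):
        code = self.condition_code
        if code not in CONDITION_AGONIST and code != "DRUG":
            raise ValidationError(f"unknown condition code {code!r}")
        if self.replicate < 1:
            raise ValidationError("replicate index must be >= 1")
        if code in CONDITION_AGONIST:
            implied = CONDITION_AGONIST[code]
            if self.agonist is None:
                object.__setattr__(self, "agonist", implied)
            elif self.agonist != implied:
                raise ValidationError(
                    f"condition {code} implies agonist {implied!r}, got {self.agonist!r}"
                )
            object.__setattr__(self, "her2_blocked", code.startswith("CDF"))
        if self.agonist is not None and self.agonist not in AGONISTS:
            raise ValidationError(f"unknown agonist {self.agonist!r}")
        if self.agonist is not None and self.agonist_dose_molar is None:
            if self.agonist in DEFAULT_AGONIST_DOSE_M:
                object.__setattr__(
                    self, "agonist_dose_molar", DEFAULT_AGONIST_DOSE_M[self.agonist]
                )
        if self.agonist is None and self.agonist_dose_molar:
            raise ValidationError("agonist dose given without an agonist")


@dataclass(frozen=True)
class PlateLayout:
    """Mapping from well id to its :class:`WellCondition`."""

    wells: Mapping[str, WellCondition]

    def __post_init__(self):
        object.__setattr__(self, "wells", dict(self.wells))
        seen: set[tuple[str, str, int]] = set()
        patients_with_control: set[str] = set()
        patients: set[str] = set()
        for well_id, cond in self.wells.items():
            patients.add(cond.patient_id)
            if cond.condition_code == "C":
                patients_with_control.add(cond.patient_id)
            key = (cond.patient_id, cond.condition_code, cond.replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate replicate index for {key} (well {well_id})"
                )
            seen.add(key)
        missing = patients - patients_with_control
        if missing:
            raise ValidationError(
                f"patients without a control (C) well: {sorted(missing)}"
            )

    def patients(self) -> list[str]:
        return sorted({c.patient_id for c in self.wells.values()})

    def wells_for(self, patient_id: str, condition_code: str | None = None
                  ) -> dict[str, WellCondition]:
        out = {}
        for well_id, cond in self.wells.items():
            if cond.patient_id != patient_id:
                continue
            if condition_code is not None and cond.condition_code != condition_code:
                continue
            out[well_id] = cond
        return out


@dataclass(frozen=True)
class RunConfig:
    """Structured run configuration for the end-to-end pipeline.

    Cutoffs are in signaling units.  The c-Met cutoff defaults to the
    clinically reported 250; HER-family cutoffs are package defaults (the
    underlying assay publication does not print them) and should be treated
    as configuration, not as established clinical values.
    """

    window_min: int = 240
    cutoffs: Mapping[str, float] = field(
        default_factory=lambda: {"cMet": 250.0, "HER1": 250.0,
                                 "HER2": 250.0, "HER3_4": 250.0}
    )
    k_range: tuple[int, ...] = (1, 2, 3)
    em_tol: float = 1e-8
    n_restarts: int = 10
    n_bootstrap: int = 199
    seed: int = 0
    dr_model: str = "four_pl"
    epsilon: float = 0.01
    ci_form: str = "mutually_exclusive"
    max_fp: float = 0.01
    simulate: bool = False
    n_patients: int = 79
    n_positive: int | None = None
    output_dir: str = "celsignal_out"

    def __post_init__(self):
        if self.window_min <= 0:
            raise ConfigError("window_min must be > 0")
        if not all(1 <= k <= 5 for k in self.k_range):
            raise ConfigError("k_range entries must be in 1..5")
        if not (0 < self.epsilon < 0.1):
            raise ConfigError("epsilon must be in (0, 0.1)")
        if self.ci_form not in ("mutually_exclusive", "non_exclusive"):
            raise ConfigError(f"unknown CI form {self.ci_form!r}")
        if "cMet" not in self.cutoffs:
            raise ConfigError("cutoffs must include cMet")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cutoffs"] = dict(self.cutoffs)
        d["k_range"] = list(self.k_range)
        return d


# ---------------------------------------------------------------------------
# plate traces
# ---------------------------------------------------------------------------

def read_plate(trace_csv_path, layout_path) -> tuple[list[ImpedanceTrace], PlateLayout]:
    """Read a plate trace CSV and its layout; validate their consistency.

    Every well column of the CSV must be described by the layout.  Layout
    wells absent from the CSV are ignored (logged), so one layout can serve
    several partial plates.
    """
    layout = read_layout(layout_path)
    df = pd.read_csv(trace_csv_path, float_precision="round_trip")
    if "time_min" not in df.columns:
        raise FormatError(f"{trace_csv_path}: missing 'time_min' column")
    times = df["time_min"].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValidationError(f"{trace_csv_path}: time_min not strictly increasing")
    well_cols = [c for c in df.columns if c != "time_min"]
    if not well_cols:
        raise FormatError(f"{trace_csv_path}: no well columns")
    missing = [w for w in well_cols if w not in layout.wells]
    if missing:
        raise ValidationError(
            f"{trace_csv_path}: wells not described by layout: {missing}"
        )
    unused = sorted(set(layout.wells) - set(well_cols))
    if unused:
        logger.info("layout wells without trace columns ignored: %s", unused)
    traces = [
        ImpedanceTrace(w, times, df[w].to_numpy(dtype=float)) for w in well_cols
    ]
    logger.info("read %d traces x %d samples from %s",
                len(traces), len(times), trace_csv_path)
    return traces, layout


def write_plate(traces: Sequence[ImpedanceTrace], path) -> None:
    """Write traces sharing a time grid to a single CSV."""
    if not traces:
        raise ValidationError("no traces to write")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.size != t0.size or not np.array_equal(tr.times, t0):
            raise ValidationError("traces do not share a time grid")
    cols = {"time_min": t0}
    cols.update({tr.well_id: tr.cell_index for tr in traces})
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _condition_from_dict(well_id: str, rec: Mapping) -> WellCondition:
    if not isinstance(rec, Mapping):
        raise FormatError(f"well {well_id}: condition record must be a mapping")
    known = {"condition", "patient_id", "replicate", "agonist",
             "agonist_dose_molar", "antagonists", "her2_blocked"}
    unknown = set(rec) - known
    if unknown:
        raise FormatError(f"well {well_id}: unknown layout keys {sorted(unknown)}")
    if "condition" not in rec or "patient_id" not in rec:
        raise FormatError(f"well {well_id}: 'condition' and 'patient_id' required")
    ants = tuple(
        Antagonist(a["drug"], float(a["dose_molar"]))
        for a in rec.get("antagonists", []) or []
    )
    return WellCondition(
        condition_code=str(rec["condition"]),
        patient_id=str(rec["patient_id"]),
        replicate=int(rec.get("replicate", 1)),
        agonist=rec.get("agonist"),
        agonist_dose_molar=(None if rec.get("agonist_dose_molar") is None
                            else float(rec["agonist_dose_molar"])),
        antagonists=ants,
        her2_blocked=bool(rec.get("her2_blocked", False)),
    )


def read_layout(path) -> PlateLayout:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "wells" not in raw:
        raise FormatError(f"{path}: layout must be a mapping with a 'wells' key")
    wells = {
        str(w): _condition_from_dict(str(w), rec) for w, rec in raw["wells"].items()
    }
    return PlateLayout(wells)


def write_layout(layout: PlateLayout, path) -> None:
    wells = {}
    for well_id, c in layout.wells.items():
        rec: dict = {"condition": c.condition_code, "patient_id": c.patient_id,
                     "replicate": c.replicate}
        if c.condition_code == "DRUG":
            rec["agonist"] = c.agonist
            rec["her2_blocked"] = c.her2_blocked
        if c.agonist_dose_molar is not None:
            rec["agonist_dose_molar"] = float(c.agonist_dose_molar)
        if c.antagonists:
            rec["antagonists"] = [
                {"drug": a.drug, "dose_molar": float(a.dose_molar)}
                for a in c.antagonists
            ]
        wells[well_id] = rec
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"wells": wells}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# cohort scores
# ---------------------------------------------------------------------------

def read_cohort_scores(path) -> pd.DataFrame:
    """Read and validate a cohort score table.

    Returns a DataFrame with columns ``patient_id`` (str), ``pathway``
    (one of :data:`PATHWAYS`) and ``score`` (float, finite); exactly one
    row per (patient, pathway).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["patient_id", "pathway", "score"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: header must start with {required}")
    if df.empty:
        raise ValidationError(f"{path}: table has no rows")
    df = df[required].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    bad = sorted(set(df["pathway"]) - set(PATHWAYS))
    if bad:
        raise ValidationError(f"{path}: unknown pathway labels {bad}")
    df["score"] = df["score"].astype(float)
    if not np.all(np.isfinite(df["score"])):
        raise ValidationError(f"{path}: non-finite scores")
    dup = df.duplicated(subset=["patient_id", "pathway"])
    if dup.any():
        rows = df.loc[dup, ["patient_id", "pathway"]].to_records(index=False)
        raise ValidationError(f"{path}: duplicate (patient, pathway) rows: {list(rows)[:5]}")
    return df.reset_index(drop=True)


def write_cohort_scores(df: pd.DataFrame, path) -> None:
    df[["patient_id", "pathway", "score"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dose-response and xenograft tables
# ---------------------------------------------------------------------------

def read_dose_response(path) -> pd.DataFrame:
    """Read a titration table: drug, agonist, dose_molar, response."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["drug", "agonist", "dose_molar", "response"]
    if not set(required).issubset(df.columns):
        raise FormatError(f"{path}: columns must include {required}")
    df = df[required].copy()
    df["dose_molar"] = df["dose_molar"].astype(float)
    df["response"] = df["response"].astype(float)
    if (df["dose_molar"] <= 0).any():
        raise ValidationError(f"{path}: non-positive doses")
    return df


def write_dose_response(df: pd.DataFrame, path) -> None:
    df[["drug", "agonist", "dose_molar", "response"]].to_csv(path, index=False)


def read_xenograft(path) -> pd.DataFrame:
    """Read a tumor-volume table: mouse_id, arm, day, volume_mm3."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["mouse_id", "arm", "day", "volume_mm3"]
    if not set(required).issubset(df.columns):
        raise FormatError(f"{path}: columns must include {required}")
    df = df[required].copy()
    df["mouse_id"] = df["mouse_id"].astype(str)
    df["day"] = df["day"].astype(float)
    df["volume_mm3"] = df["volume_mm3"].astype(float)
    if (df["volume_mm3"] <= 0).any():
        raise ValidationError(f"{path}: non-positive tumor volumes")
    return df


def write_xenograft(df: pd.DataFrame, path) -> None:
    df[["mouse_id", "arm", "day", "volume_mm3"]].to_csv(path, index=False)
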