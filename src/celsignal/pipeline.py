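"""Config-driven orchestration: simulate/load -> score -> cohort analysis.

``run_pipeline`` executes the stages in order, writes machine-readable
outputs (JSON reports plus CSV tables) into the configured output
directory, and returns a :class:`RunManifest` listing every artifact with
its SHA-256 digest.  Outputs contain no timestamps, so a rerun with the
same config and seed produces byte-identical files and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import ConfigError, InfeasibleCutoffError, StageError
from .plate_io import (
    PlateLayout,
    RunConfig,
    read_plate,
    write_cohort_scores,
    write_layout,
    write_plate,
)
from .population_mixture import (
    MixtureModel,
    fit_mixture_em,
    lrt_num_components,
    prevalence,
    roc_from_mixture,
    select_cutoff,
)
from .scoring import PatientCall, classify_cohort, score_plate
from .synthetic_data import generate_cohort_profiles, generate_plate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunManifest:
    config: Mapping
    seed: int
    stages: tuple[str, ...]
    outputs: Mapping[str, str]  # relative path -> sha256
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config": dict(self.config),
            "seed": self.seed,
            "stages": list(self.stages),
            "outputs": dict(self.outputs),
            "version": self.version,
        }


@dataclass
class PipelineResult:
    manifest: RunManifest
    score_table: pd.DataFrame
    calls: list[PatientCall] = field(default_factory=list)
    cohort_report: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def render_patient_report(
    calls: Sequence[PatientCall],
    score_table: pd.DataFrame,
    cutoffs: Mapping[str, float],
) -> list[dict]:
    """One record per patient: scores, cutoffs used, positivity flags."""
    by_patient = {
        str(pid): dict(zip(grp["pathway"], grp["score"]))
        for pid, grp in score_table.groupby("patient_id")
    }
    records = []
    for call in calls:
        records.append({
            "patient_id": call.patient_id,
            "scores": {p: float(s) for p, s in
                       sorted(by_patient.get(call.patient_id, {}).items())},
            "cutoffs": {p: float(c) for p, c in sorted(cutoffs.items())},
            "positive": {p: bool(v) for p, v in sorted(call.positive.items())},
            "combined_positive": bool(call.combined),
        })
    return records


def _model_record(model: MixtureModel) -> dict:
    return {
        "k": model.k,
        "weights": list(model.weights),
        "means": list(model.means),
        "sds": list(model.sds),
        "log_likelihood": model.log_likelihood,
        "converged": model.converged,
        "n_iter": model.n_iter,
    }


def run_pipeline(
    config: RunConfig,
    traces_csv: str | None = None,
    layout_path: str | None = None,
) -> PipelineResult:
    """Execute the full analysis; see the module docstring.

    With ``config.simulate`` true the inputs are generated (a six-condition
    duplicate-well plate per synthetic patient); otherwise ``traces_csv``
    and ``layout_path`` must point to existing files.
    """
    out_dir = Path(config.output_dir)
    stages: list[str] = []
    outputs: dict[str, str] = {}

    def register(path: Path) -> None:
        outputs[path.name] = _sha256(path)

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate:
            out_dir.mkdir(parents=True, exist_ok=True)
            profiles = generate_cohort_profiles(
                config.n_patients, seed=config.seed,
                n_combined_positive=config.n_positive,
                cutoff=float(config.cutoffs["cMet"]),
            )
            wells: dict = {}
            all_traces = []
            for i, prof in enumerate(profiles):
                from .synthetic_data import default_plate_layout

                lay = default_plate_layout(prof.patient_id)
                renamed = {f"{prof.patient_id}_{w}": c
                           for w, c in lay.wells.items()}
                wells.update(renamed)
                plate = generate_plate(prof, PlateLayout(renamed),
                                       seed=config.seed * 100_003 + i)
                all_traces.extend(plate)
            layout = PlateLayout(wells)
            traces = all_traces
            write_plate(traces, out_dir / "traces.csv")
            write_layout(layout, out_dir / "layout.yaml")
            register(out_dir / "traces.csv")
            register(out_dir / "layout.yaml")
        else:
            if traces_csv is None or layout_path is None:
                raise ConfigError(
                    "simulate is false but traces/layout paths are missing")
            traces, layout = read_plate(traces_csv, layout_path)
            out_dir.mkdir(parents=True, exist_ok=True)
        stages.append("inputs")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("inputs", exc) from exc

    # ---- stage: scoring ------------------------------------------------
    try:
        score_table, _records = score_plate(traces, layout, config.window_min)
        write_cohort_scores(score_table, out_dir / "cohort_scores.csv")
        register(out_dir / "cohort_scores.csv")
        logger.info("scored %d patients", score_table["patient_id"].nunique())
        stages.append("scoring")
    except Exception as exc:  # noqa: BLE001
        raise StageError("scoring", exc) from exc

    # ---- stage: calls --------------------------------------------------
    try:
        calls = classify_cohort(score_table, config.cutoffs)
        patient_report = render_patient_report(calls, score_table, config.cutoffs)
        _write_json(patient_report, out_dir / "patient_report.json")
        register(out_dir / "patient_report.json")
        stages.append("calls")
    except Exception as exc:  # noqa: BLE001
        raise StageError("calls", exc) from exc

    # ---- stage: cohort -------------------------------------------------
    try:
        cmet = score_table[score_table["pathway"] == "cMet"]["score"].to_numpy()
        models = {
            k: fit_mixture_em(cmet, k, tol=config.em_tol,
                              n_restarts=config.n_restarts, seed=config.seed + k)
            for k in config.k_range
        }
        lrt = {}
        ks = sorted(config.k_range)
        for k0, k1 in zip(ks, ks[1:]):
            res = lrt_num_components(
                cmet, k0, k1, n_bootstrap=config.n_bootstrap,
                seed=config.seed + 97 * k1, tol=config.em_tol,
                n_restarts=config.n_restarts)
            lrt[f"{k0}_vs_{k1}"] = {"statistic": res.statistic,
                                    "p_value": res.p_value}
        best_k = max(k for k in ks if k >= 2) if any(k >= 2 for k in ks) else None
        cohort_report: dict = {
            "n_patients": int(score_table["patient_id"].nunique()),
            "models": {str(k): _model_record(m) for k, m in models.items()},
            "lrt": lrt,
        }
        if best_k is not None:
            roc = roc_from_mixture(models[best_k])
            try:
                chosen = select_cutoff(roc, config.max_fp)
                cohort_report["cutoff"] = {
                    "cutoff": chosen.cutoff,
                    "sensitivity": chosen.sensitivity,
                    "false_positive_rate": chosen.false_positive_rate,
                    "max_fp": config.max_fp,
                }
            except InfeasibleCutoffError as exc:
                cohort_report["cutoff"] = {"error": str(exc)}
            cohort_report["roc"] = [
                {"cutoff": r.cutoff, "sensitivity": r.sensitivity,
                 "false_positive_rate": r.false_positive_rate}
                for r in roc
            ]
        n_pos = sum(1 for c in calls if c.combined)
        prev = prevalence(n_pos, len(calls))
        cohort_report["prevalence"] = {
            "n_pos": prev.n_pos, "n": prev.n, "proportion": prev.proportion,
            "ci_lower": prev.ci_lower, "ci_upper": prev.ci_upper,
            "ci_method": prev.ci_method, "level": prev.level,
        }
        _write_json(cohort_report, out_dir / "cohort_report.json")
        register(out_dir / "cohort_report.json")
        stages.append("cohort")
    except Exception as exc:  # noqa: BLE001
        raise StageError("cohort", exc) from exc

    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, stages=tuple(stages),
        outputs=outputs,
    )
    _write_json(manifest.to_dict(), out_dir / "manifest.json")
    return PipelineResult(manifest, score_table, calls, cohort_report)
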