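"""Session-table CSV I/O, configuration loading, and the pipeline driver.

A cohort is interchanged as two CSVs: ``sessions.csv`` with one row per
session (prescription fields and labels) and ``timepoints.csv`` in long
form with one row per (session, grid point) carrying the four vitals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import RFConfig, ScoreRecord, loocv_scores
from .cohort import (N_TIMEPOINTS, CohortConfig, CorrTargets, PatientProfile,
                     SessionRecord, simulate_cohort)
from .evaluate import scores_report
from .exceptions import SchemaError

logger = logging.getLogger(__name__)

SESSIONS_COLUMNS = [
    "session_id", "patient_id", "dry_weight", "target_end_weight",
    "hourly_weight_loss", "prev_end_weight", "symptomatic", "onset_index",
    "is_synthetic",
]
TIMEPOINTS_COLUMNS = [
    "session_id", "timepoint_index", "minutes", "sbp", "dbp", "hr", "weight",
]


def _r(value: float) -> str:
    # shortest round-trippable decimal form, so write -> read is lossless
    return repr(float(value))


def write_sessions(sessions: Sequence[SessionRecord], out_dir: str | Path
                   ) -> tuple[Path, Path]:
    """Write a cohort to ``sessions.csv`` + ``timepoints.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    head = pd.DataFrame([{
        "session_id": s.session_id, "patient_id": s.patient_id,
        "dry_weight": _r(s.dry_weight), "target_end_weight": _r(s.target_end_weight),
        "hourly_weight_loss": _r(s.hourly_weight_loss),
        "prev_end_weight": _r(s.prev_end_weight),
        "symptomatic": int(s.symptomatic),
        "onset_index": "" if s.onset_index is None else int(s.onset_index),
        "is_synthetic": int(s.is_synthetic),
    } for s in sessions], columns=SESSIONS_COLUMNS)
    points = pd.DataFrame([{
        "session_id": s.session_id, "timepoint_index": j, "minutes": 30 * j,
        "sbp": _r(s.sbp[j]), "dbp": _r(s.dbp[j]), "hr": _r(s.hr[j]),
        "weight": _r(s.weight[j]),
    } for s in sessions for j in range(N_TIMEPOINTS)], columns=TIMEPOINTS_COLUMNS)
    sessions_path = out_dir / "sessions.csv"
    timepoints_path = out_dir / "timepoints.csv"
    head.to_csv(sessions_path, index=False)
    points.to_csv(timepoints_path, index=False)
    return sessions_path, timepoints_path


def read_sessions(sessions_path: str | Path, timepoints_path: str | Path
                  ) -> list[SessionRecord]:
    """Read and validate a cohort from the two-CSV schema.

    Schema violations raise :class:`SchemaError` naming the offending
    column or rows; sessions missing grid points are retained with NaN
    vitals (imputed downstream) under a warning.
    """
    head = pd.read_csv(sessions_path, float_precision="round_trip")
    points = pd.read_csv(timepoints_path, float_precision="round_trip")
    for col in SESSIONS_COLUMNS:
        if col not in head.columns:
            raise SchemaError(f"sessions file missing required column {col!r}")
    for col in TIMEPOINTS_COLUMNS:
        if col not in points.columns:
            raise SchemaError(f"timepoints file missing required column {col!r}")

    for col in ("sbp", "dbp", "hr", "weight"):
        numeric = pd.to_numeric(points[col], errors="coerce")
        bad = points.index[numeric.isna() & points[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric {col!r} values at timepoints rows {list(bad + 2)}")
        points[col] = numeric
    dup = points.duplicated(subset=["session_id", "timepoint_index"], keep=False)
    if dup.any():
        raise SchemaError(
            "duplicate (session, timepoint) pairs at timepoints rows "
            f"{list(points.index[dup] + 2)}")
    dup_s = head.duplicated(subset=["session_id"], keep=False)
    if dup_s.any():
        raise SchemaError(
            f"duplicate session_id at sessions rows {list(head.index[dup_s] + 2)}")

    grouped = {sid: g for sid, g in points.groupby("session_id")}
    records = []
    for _, row in head.iterrows():
        sid = row["session_id"]
        grid = {name: np.full(N_TIMEPOINTS, np.nan)
                for name in ("sbp", "dbp", "hr", "weight")}
        g = grouped.get(sid)
        if g is not None:
            idx = g["timepoint_index"].astype(int).to_numpy()
            if np.any((idx < 0) | (idx >= N_TIMEPOINTS)):
                raise SchemaError(f"session {sid}: timepoint_index out of 0..8")
            for name in grid:
                grid[name][idx] = g[name].to_numpy(float)
        n_present = int(np.sum(~np.isnan(grid["sbp"])))
        if n_present < N_TIMEPOINTS:
            warnings.warn(
                f"session {sid}: only {n_present}/{N_TIMEPOINTS} grid points; "
                "missing vitals will be imputed downstream")
        onset = row["onset_index"]
        onset = None if pd.isna(onset) else int(onset)
        records.append(SessionRecord(
            patient_id=str(row["patient_id"]), session_id=str(sid),
            sbp=grid["sbp"], dbp=grid["dbp"], hr=grid["hr"],
            weight=grid["weight"],
            dry_weight=float(row["dry_weight"]),
            target_end_weight=float(row["target_end_weight"]),
            hourly_weight_loss=float(row["hourly_weight_loss"]),
            prev_end_weight=float(row["prev_end_weight"]),
            symptomatic=bool(int(row["symptomatic"])),
            onset_index=onset,
            is_synthetic=bool(int(row["is_synthetic"])),
        ))
    return records


def write_scores(records: Sequence[ScoreRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> list[ScoreRecord]:
    frame = pd.read_csv(path)
    return [ScoreRecord(str(r.session_id), float(r.score_rf1), float(r.score_rf2),
                        float(r.score_fused), int(r.label_rf1), int(r.label_rf2))
            for r in frame.itertuples()]


@dataclass
class PipelineConfig:
    """End-to-end run parameters; the master seed derives all stage seeds."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    oversample_k: float = 1.0
    rf: RFConfig = field(default_factory=RFConfig)
    output_dir: str = "hdrisk_run"
    seed: int = 0
    log_level: str = "INFO"

    def stage_seeds(self) -> dict[str, int]:
        # counter-based derivation: position i is stable even if later
        # stages are added
        state = np.random.SeedSequence(self.seed).generate_state(4, dtype=np.uint32)
        return {"simulate": int(state[0]), "loocv": int(state[1])}


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=lambda o: list(o)
                                 if isinstance(o, (tuple, np.ndarray)) else str(o)))


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON mapping file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = dict(raw.get("cohort", {}))
    if "profiles" in cohort_raw:
        cohort_raw["profiles"] = [PatientProfile(**p) for p in cohort_raw["profiles"]]
    if "corr_targets" in cohort_raw:
        cohort_raw["corr_targets"] = CorrTargets(**cohort_raw["corr_targets"])
    rf_raw = dict(raw.get("rf", {}))
    return PipelineConfig(
        cohort=CohortConfig(**cohort_raw),
        oversample_k=float(raw.get("oversample_k", 1.0)),
        rf=RFConfig(**rf_raw),
        output_dir=str(raw.get("output_dir", "hdrisk_run")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """simulate -> featurize -> LOOCV train/eval -> report; returns the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    logging.basicConfig(level=config.log_level)

    logger.info("stage: simulate")
    cohort_config = dataclasses.replace(config.cohort, seed=seeds["simulate"])
    cohort = simulate_cohort(cohort_config)
    write_sessions(cohort, out)

    logger.info("stage: loocv train/eval")
    records = loocv_scores(cohort, config.rf, k=config.oversample_k,
                           seed=seeds["loocv"])
    write_scores(records, out / "scores.csv")

    logger.info("stage: report")
    if records:
        report = scores_report(records)
    else:
        warnings.warn("no scorable folds; writing an empty report")
        report = pd.DataFrame(columns=["stage", "auc", "auc_se", "cutoff",
                                       "accuracy", "sensitivity", "specificity",
                                       "n_pos", "n_neg"])
    report.to_csv(out / "report.csv", index=False)

    import sklearn

    manifest = {
        "config": _config_dict(config),
        "stage_seeds": seeds,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scikit-learn": sklearn.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
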