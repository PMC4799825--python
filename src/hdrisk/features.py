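"""Engineered features and label vectors for the two-stage classifier.

Stage ``RF1`` scores a session one hour into treatment (vitals at T0 and
T2, pressure criticality at T1/T2); stage ``RF2`` scores it again at three
hours (vitals at T0 and T6, criticality at T5/T6).  Both stages add the
prescription fields and the interdialytic weight gain, for 13 numeric
features per row.  Labels follow the 0 = symptomatic / 1 = nonsymptomatic
encoding; RF2 counts a session as positive only when symptom onset falls
in the last treatment hour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import LAST_HOUR_INDICES, SessionRecord

Stage = Literal["RF1", "RF2"]

#: grid index of each stage's late vitals measurement
STAGE_LATE_INDEX = {"RF1": 2, "RF2": 6}
#: grid indices of each stage's two pressure-criticality indicators
STAGE_PP_INDICES = {"RF1": (1, 2), "RF2": (5, 6)}

SYMPTOMATIC_LABEL = 0
NONSYMPTOMATIC_LABEL = 1

FEATURE_COLUMNS = [
    "sbp_start", "dbp_start", "hr_start", "weight_start",
    "sbp_late", "dbp_late", "hr_late", "weight_late",
    "hourly_weight_loss", "target_end_weight", "interdialytic_gain",
    "pp_a", "pp_b",
]


def interdialytic_weight_gain(weight_t0: float, prev_end_weight: float,
                              dry_weight: float) -> float:
    """Fractional weight gained since the previous session's end.

    ``(weight_t0 - prev_end_weight) / dry_weight``; may be negative.
    """
    if dry_weight <= 0:
        raise ValueError(f"dry_weight must be > 0, got {dry_weight}")
    return (weight_t0 - prev_end_weight) / dry_weight


def critical_indicator(sbp_initial: float, sbp_current: float) -> float:
    """Pressure criticality score in [0, 1].

    Sessions starting at or below 100 mmHg systolic are scored 0 (the
    indicator targets pressures *falling* from above 100 toward 90).
    Otherwise: 1 when the current SBP is at or below 90 mmHg, 0 at or above
    100 mmHg, linear in between.
    """
    if sbp_initial <= 0 or sbp_current <= 0:
        raise ValueError("pressures must be > 0")
    if sbp_initial <= 100:
        return 0.0
    if sbp_current <= 90:
        return 1.0
    if sbp_current >= 100:
        return 0.0
    return 1.0 - (sbp_current - 90.0) / 10.0


def _imputed(values: np.ndarray, name: str) -> np.ndarray:
    """Fill missing grid vitals by last observation carried forward."""
    arr = np.asarray(values, float)
    if np.isnan(arr[0]):
        raise ValueError(f"{name} missing at T0; cannot impute the session start")
    if np.any(np.isnan(arr)):
        arr = arr.copy()
        for j in range(1, arr.size):
            if np.isnan(arr[j]):
                arr[j] = arr[j - 1]
    return arr


@dataclass
class FeatureVector:
    """The classifier input row for one session at one stage."""

    stage: Stage
    sbp_start: float
    dbp_start: float
    hr_start: float
    weight_start: float
    sbp_late: float
    dbp_late: float
    hr_late: float
    weight_late: float
    hourly_weight_loss: float
    target_end_weight: float
    interdialytic_gain: float
    pp_a: float
    pp_b: float
    label: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], float)


def build_labels(session: SessionRecord, stage: Stage) -> int:
    """0 = positive (symptomatic) for the stage, 1 otherwise.

    RF1 counts any symptomatic session; RF2 only those with onset in the
    last treatment hour — earlier-onset sessions are labeled 1 for RF2.
    """
    if stage not in STAGE_LATE_INDEX:
        raise ValueError(f"unknown stage {stage!r}")
    if not session.symptomatic:
        return NONSYMPTOMATIC_LABEL
    if stage == "RF1":
        return SYMPTOMATIC_LABEL
    return (SYMPTOMATIC_LABEL if session.onset_index in LAST_HOUR_INDICES
            else NONSYMPTOMATIC_LABEL)


def build_features(session: SessionRecord, stage: Stage) -> FeatureVector:
    if stage not in STAGE_LATE_INDEX:
        raise ValueError(f"unknown stage {stage!r}")
    late = STAGE_LATE_INDEX[stage]
    pp_i, pp_j = STAGE_PP_INDICES[stage]
    sbp = _imputed(session.sbp, "sbp")
    dbp = _imputed(session.dbp, "dbp")
    hr = _imputed(session.hr, "hr")
    weight = _imputed(session.weight, "weight")
    return FeatureVector(
        stage=stage,
        sbp_start=sbp[0], dbp_start=dbp[0], hr_start=hr[0], weight_start=weight[0],
        sbp_late=sbp[late], dbp_late=dbp[late], hr_late=hr[late],
        weight_late=weight[late],
        hourly_weight_loss=session.hourly_weight_loss,
        target_end_weight=session.target_end_weight,
        interdialytic_gain=interdialytic_weight_gain(
            weight[0], session.prev_end_weight, session.dry_weight),
        pp_a=critical_indicator(sbp[0], sbp[pp_i]),
        pp_b=critical_indicator(sbp[0], sbp[pp_j]),
        label=build_labels(session, stage),
    )


def feature_matrix(sessions: Sequence[SessionRecord], stage: Stage
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature rows and labels for a list of sessions."""
    vecs = [build_features(s, stage) for s in sessions]
    x = np.stack([v.as_array() for v in vecs]) if vecs else np.empty((0, 13))
    y = np.array([v.label for v in vecs], int)
    return x, y
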