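"""Synthetic hemodialysis cohort generation and statistical verification.

A cohort is a list of :class:`SessionRecord` objects, one per dialysis
session.  Each session carries a 9-point vitals grid (systolic/diastolic
blood pressure, heart rate, weight at 0, 30, ..., 240 minutes), the
prescription fields set by the clinician (dry weight, target end-of-session
weight, hourly weight loss) and the outcome label (symptomatic flag plus the
timepoint index at which symptoms started).

The generator draws each session's vitals from per-patient normal
distributions, applies per-timepoint class mean shifts to symptomatic
sessions, and induces a cross-parameter correlation structure
(weight <-> pressures/heart-rate per timepoint and per class, SBP <-> DBP
per timepoint, near-unit weight autocorrelation) through the triangular
correlation-induction machinery of :mod:`hdrisk.oversample`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InsufficientDataError
from .oversample import nearest_correlation

logger = logging.getLogger(__name__)

N_TIMEPOINTS = 9
TIMEPOINT_MINUTES = tuple(30 * a for a in range(N_TIMEPOINTS))

#: Indices counted as "last hour of treatment" for symptom onset.
LAST_HOUR_INDICES = (7, 8)


@dataclass
class PatientProfile:
    """Per-patient generative parameters (means/SDs of the monitored vitals)."""

    patient_id: str
    age: int
    sex: str
    n_symptomatic_sessions: int
    weight_mean: float
    weight_sd: float
    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float
    hr_mean: float
    hr_sd: float

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ConfigurationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("weight_sd", "sbp_sd", "dbp_sd", "hr_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0 for {self.patient_id}")
        if self.n_symptomatic_sessions < 0:
            raise ConfigurationError("n_symptomatic_sessions must be >= 0")


@dataclass
class SessionRecord:
    """One dialysis session: vitals grid, prescription fields, outcome label.

    Vitals arrays have exactly 9 entries on the 0..240-minute grid.  NaN
    entries denote missing measurements (imputed downstream); non-missing
    vitals must be strictly positive.  ``onset_index`` is present iff the
    session is symptomatic, and indexes the grid point (1..8) at which
    symptoms started.
    """

    patient_id: str
    session_id: str
    sbp: np.ndarray
    dbp: np.ndarray
    hr: np.ndarray
    weight: np.ndarray
    dry_weight: float
    target_end_weight: float
    hourly_weight_loss: float
    prev_end_weight: float
    symptomatic: bool
    onset_index: int | None = None
    is_synthetic: bool = False

    timepoint_minutes: tuple = TIMEPOINT_MINUTES

    def __post_init__(self) -> None:
        for name in ("sbp", "dbp", "hr", "weight"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_TIMEPOINTS,):
                raise ConfigurationError(
                    f"{name} must have exactly {N_TIMEPOINTS} grid points, "
                    f"got shape {arr.shape}"
                )
            finite = arr[~np.isnan(arr)]
            if np.any(finite <= 0):
                raise ConfigurationError(f"{name} must be strictly positive")
            setattr(self, name, arr)
        if self.symptomatic:
            if self.onset_index is None:
                raise ConfigurationError("symptomatic session requires onset_index")
            if not 1 <= int(self.onset_index) <= 8:
                raise ConfigurationError("onset_index must be in 1..8")
        elif self.onset_index is not None:
            raise ConfigurationError("onset_index present on nonsymptomatic session")


def default_profiles() -> list[PatientProfile]:
    """Ten-patient study-emulating profile set (7 M / 3 F, 17 critical events)."""
    rows = [
        ("pt01", 66, "M", 0, 80.6, 3.3, 143.2, 8.2, 70.4, 4.2, 68.6, 3.5),
        ("pt02", 65, "M", 3, 93.7, 3.8, 118.2, 8.3, 64.6, 3.7, 58.1, 4.1),
        ("pt03", 65, "M", 5, 72.1, 3.1, 111.9, 10.8, 54.5, 6.2, 78.0, 4.5),
        ("pt04", 65, "M", 6, 80.0, 3.3, 117.4, 9.3, 65.0, 5.8, 67.4, 5.3),
        ("pt05", 37, "M", 2, 60.2, 3.0, 109.5, 7.3, 71.9, 4.9, 66.5, 4.6),
        ("pt06", 47, "M", 0, 47.9, 2.4, 130.5, 4.7, 74.5, 3.4, 72.8, 3.3),
        ("pt07", 52, "M", 0, 82.7, 5.2, 116.4, 6.5, 75.9, 4.3, 67.2, 4.2),
        ("pt08", 67, "F", 0, 62.0, 2.9, 131.3, 7.9, 82.5, 4.0, 69.8, 3.1),
        ("pt09", 69, "F", 1, 61.8, 2.6, 151.6, 8.7, 84.2, 5.6, 69.3, 4.6),
        ("pt10", 68, "F", 0, 92.0, 3.7, 124.3, 7.9, 59.5, 4.1, 70.3, 3.8),
    ]
    return [PatientProfile(*row) for row in rows]


# Symptomatic-minus-asymptomatic mean shifts (mmHg) per timepoint.
DEFAULT_SBP_SHIFT = (-7.86, -9.34, -7.33, -12.53, -13.80, -16.69, -16.43, -22.70, -21.52)
DEFAULT_DBP_SHIFT = (-4.43, -5.92, -4.68, -6.01, -7.22, -8.80, -8.21, -12.97, -7.39)


@dataclass
class CorrTargets:
    """Per-timepoint cross-parameter correlation targets, one set per class."""

    weight_sbp_asymptomatic: tuple = (0.04, -0.11, -0.15, -0.15, -0.16, -0.22, -0.28, -0.33, -0.30)
    weight_dbp_asymptomatic: tuple = (-0.49, -0.45, -0.50, -0.55, -0.49, -0.45, -0.47, -0.46, -0.64)
    weight_hr_asymptomatic: tuple = (-0.25, -0.29, -0.25, -0.25, -0.23, -0.29, -0.35, -0.33, -0.30)
    weight_sbp_symptomatic: tuple = (-0.59, -0.22, -0.22, -0.13, -0.18, -0.06, -0.31, 0.23, -0.15)
    weight_dbp_symptomatic: tuple = (-0.63, -0.35, 0.13, -0.04, -0.15, -0.19, -0.16, 0.06, -0.16)
    weight_hr_symptomatic: tuple = (-0.53, -0.46, -0.47, -0.43, -0.34, -0.47, -0.54, -0.29, -0.34)
    sbp_dbp: tuple = (0.76, 0.76, 0.83, 0.83, 0.84, 0.80, 0.85, 0.57, 0.70)
    #: correlation between the start weight and every later-timepoint weight
    weight_autocorr: float = 0.99
    #: correlation between the target end-of-session weight and the start weight
    target_start: float = 0.99
    #: correlation between interdialytic weight gain and hourly weight loss
    gain_hourly_loss: float = 0.48

    def __post_init__(self) -> None:
        for name in (
            "weight_sbp_asymptomatic", "weight_dbp_asymptomatic", "weight_hr_asymptomatic",
            "weight_sbp_symptomatic", "weight_dbp_symptomatic", "weight_hr_symptomatic",
            "sbp_dbp",
        ):
            vals = np.asarray(getattr(self, name), float)
            if vals.shape != (N_TIMEPOINTS,):
                raise ConfigurationError(f"{name} needs {N_TIMEPOINTS} entries")
            if np.any(np.abs(vals) > 1):
                raise ConfigurationError(f"{name} entries must lie in [-1, 1]")
        for name in ("weight_autocorr", "target_start", "gain_hourly_loss"):
            if abs(getattr(self, name)) > 1:
                raise ConfigurationError(f"{name} must lie in [-1, 1]")


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    profiles: list[PatientProfile] = field(default_factory=default_profiles)
    sessions_per_patient: int = 20
    class_shift_sbp: tuple = DEFAULT_SBP_SHIFT
    class_shift_dbp: tuple = DEFAULT_DBP_SHIFT
    corr_targets: CorrTargets = field(default_factory=CorrTargets)
    frac_last_hour_onsets: float = 14.0 / 17.0
    hourly_loss_mean: float = 0.5
    hourly_loss_sd: float = 0.15
    dry_weight_offset: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sessions_per_patient < 1:
            raise ConfigurationError("sessions_per_patient must be >= 1")
        for name in ("class_shift_sbp", "class_shift_dbp"):
            if len(getattr(self, name)) != N_TIMEPOINTS:
                raise ConfigurationError(f"{name} needs {N_TIMEPOINTS} entries")
        if not 0 <= self.frac_last_hour_onsets <= 1:
            raise ConfigurationError("frac_last_hour_onsets must lie in [0, 1]")
        for p in self.profiles:
            if p.n_symptomatic_sessions > self.sessions_per_patient:
                raise ConfigurationError(
                    f"{p.patient_id}: n_symptomatic_sessions "
                    f"({p.n_symptomatic_sessions}) exceeds sessions_per_patient "
                    f"({self.sessions_per_patient})"
                )

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_patient * len(self.profiles)

    @property
    def n_symptomatic(self) -> int:
        return sum(p.n_symptomatic_sessions for p in self.profiles)


# Variable order of the per-session correlated draw: weights, SBPs, DBPs,
# HRs by timepoint, then the target end weight.  Fixed so that the
# triangular factorization (and hence every cohort) is seed-reproducible.
_W = slice(0, 9)
_S = slice(9, 18)
_D = slice(18, 27)
_H = slice(27, 36)
_TGT = 36
_N_VARS = 37


def session_corr_matrix(targets: CorrTargets, symptomatic: bool) -> np.ndarray:
    """Assemble the 37x37 target correlation matrix for one session class.

    Only the pairs with stated targets are filled directly; cross-timepoint
    weight<->vital entries are propagated through the near-unit weight
    autocorrelation (the grid weights are almost interchangeable), and the
    remaining vital<->vital entries are filled with their common-weight-
    factor implication (the product of the two weight correlations), which
    keeps the stated entries nearly intact after the positive-definite
    repair.
    """
    cls = "symptomatic" if symptomatic else "asymptomatic"
    w_sbp = np.asarray(getattr(targets, f"weight_sbp_{cls}"), float)
    w_dbp = np.asarray(getattr(targets, f"weight_dbp_{cls}"), float)
    w_hr = np.asarray(getattr(targets, f"weight_hr_{cls}"), float)
    sbp_dbp = np.asarray(targets.sbp_dbp, float)
    rho_w = targets.weight_autocorr

    c = np.eye(_N_VARS)
    vitals = {9: w_sbp, 18: w_dbp, 27: w_hr}
    for j in range(N_TIMEPOINTS):
        for k in range(N_TIMEPOINTS):
            if j != k:
                c[j, k] = rho_w
            # weight_k vs vital_j: full target on the diagonal (k == j),
            # damped by the weight autocorrelation off it.
            damp = 1.0 if k == j else rho_w
            for base, wv in vitals.items():
                c[k, base + j] = c[base + j, k] = damp * wv[j]
            # vital<->vital entries without a stated target: fill with the
            # common-weight-factor implication
            for base_a, wa in vitals.items():
                for base_b, wb in vitals.items():
                    if base_a < base_b or (base_a == base_b and k > j):
                        c[base_a + j, base_b + k] = c[base_b + k, base_a + j] \
                            = wa[j] * wb[k]
        c[9 + j, 18 + j] = c[18 + j, 9 + j] = sbp_dbp[j]
        # the target end weight behaves like one more weight column
        c[_TGT, j] = c[j, _TGT] = targets.target_start
        for base, wv in vitals.items():
            c[_TGT, base + j] = c[base + j, _TGT] = targets.target_start * wv[j]
    return nearest_correlation(c)


def simulate_cohort(config: CohortConfig) -> list[SessionRecord]:
    """Generate a full synthetic cohort, deterministic given ``config.seed``.

    The symptomatic count and its per-patient allocation are hard
    constraints taken from the profiles; ``round(frac_last_hour_onsets *
    n_symptomatic)`` symptomatic sessions get a last-hour onset (index 7 or
    8), the rest an onset drawn uniformly from 1..6.
    """
    rng = np.random.default_rng(config.seed)
    chol = {
        cls: np.linalg.cholesky(session_corr_matrix(config.corr_targets, cls))
        for cls in (False, True)
    }
    shift_sbp = np.asarray(config.class_shift_sbp, float)
    shift_dbp = np.asarray(config.class_shift_dbp, float)
    rho_g = config.corr_targets.gain_hourly_loss

    sessions: list[SessionRecord] = []
    for prof in config.profiles:
        sympt_slots = set(
            rng.choice(config.sessions_per_patient, size=prof.n_symptomatic_sessions,
                       replace=False).tolist()
        )
        dry_weight = prof.weight_mean - config.dry_weight_offset
        if dry_weight <= 0:
            raise ConfigurationError(f"{prof.patient_id}: nonpositive dry weight")
        # pseudo end weight of the (unobserved) session before the first one
        prev_end = (prof.weight_mean - 2 * config.hourly_loss_mean
                    + prof.weight_sd * rng.standard_normal())
        mu_gain = 4 * config.hourly_loss_mean / dry_weight
        sd_gain = np.sqrt(2.0) * prof.weight_sd / dry_weight

        for t in range(config.sessions_per_patient):
            symptomatic = t in sympt_slots
            x = chol[symptomatic] @ rng.standard_normal(_N_VARS)

            # hourly weight loss correlated with the interdialytic gain
            approx_w0 = (prof.weight_mean + 2 * config.hourly_loss_mean
                         + prof.weight_sd * x[0])
            gain = (approx_w0 - prev_end) / dry_weight
            hwl = (config.hourly_loss_mean
                   + rho_g * config.hourly_loss_sd * (gain - mu_gain) / sd_gain
                   + np.sqrt(1 - rho_g ** 2) * config.hourly_loss_sd
                   * rng.standard_normal())
            hwl = max(hwl, 0.05)

            trend = (4 - np.arange(N_TIMEPOINTS)) * hwl / 2.0
            weight = prof.weight_mean + trend + prof.weight_sd * x[_W]
            sbp = prof.sbp_mean + prof.sbp_sd * x[_S]
            dbp = prof.dbp_mean + prof.dbp_sd * x[_D]
            hr = prof.hr_mean + prof.hr_sd * x[_H]
            if symptomatic:
                sbp = sbp + shift_sbp
                dbp = dbp + shift_dbp
            target_end = (prof.weight_mean - 2 * config.hourly_loss_mean
                          + prof.weight_sd * x[_TGT])

            sessions.append(SessionRecord(
                patient_id=prof.patient_id,
                session_id=f"{prof.patient_id}-s{t:03d}",
                sbp=np.maximum(sbp, 1e-3),
                dbp=np.maximum(dbp, 1e-3),
                hr=np.maximum(hr, 1e-3),
                weight=np.maximum(weight, 1e-3),
                dry_weight=dry_weight,
                target_end_weight=target_end,
                hourly_weight_loss=hwl,
                prev_end_weight=prev_end,
                symptomatic=symptomatic,
                onset_index=1 if symptomatic else None,  # placeholder, set below
            ))
            prev_end = float(sessions[-1].weight[8])

    _assign_onsets(sessions, config.frac_last_hour_onsets, rng)
    logger.info("simulated %d sessions (%d symptomatic)",
                len(sessions), sum(s.symptomatic for s in sessions))
    return sessions


def _assign_onsets(sessions: Sequence[SessionRecord], frac_last_hour: float,
                   rng: np.random.Generator) -> None:
    sympt_idx = [i for i, s in enumerate(sessions) if s.symptomatic]
    n_last = int(round(frac_last_hour * len(sympt_idx)))
    last = set(rng.choice(len(sympt_idx), size=n_last, replace=False).tolist()) \
        if sympt_idx else set()
    for rank, i in enumerate(sympt_idx):
        if rank in last:
            sessions[i].onset_index = int(rng.choice(LAST_HOUR_INDICES))
        else:
            sessions[i].onset_index = int(rng.integers(1, 7))


@dataclass
class StatReport:
    """Recovered cohort statistics: class mean differences and correlations.

    ``class_differences`` has one row per (timepoint, parameter) with the
    symptomatic-minus-asymptomatic mean difference, Welch t statistic and
    p-value.  ``correlations`` has one row per (class, timepoint, pair) with
    the Pearson coefficient and its significance.
    """

    class_differences: pd.DataFrame
    correlations: pd.DataFrame


def verify_cohort_stats(cohort: Sequence[SessionRecord],
                        config: CohortConfig | None = None) -> StatReport:
    """Recompute the class-difference t-tests and per-class Pearson correlations."""
    sympt = [s for s in cohort if s.symptomatic]
    asympt = [s for s in cohort if not s.symptomatic]
    if len(sympt) < 3 or len(asympt) < 3:
        raise InsufficientDataError(
            f"need >= 3 sessions per class, got {len(sympt)} symptomatic / "
            f"{len(asympt)} nonsymptomatic"
        )

    def grid(sessions, name):
        return np.stack([getattr(s, name) for s in sessions])

    diffs = []
    for name in ("sbp", "dbp", "hr"):
        a, b = grid(sympt, name), grid(asympt, name)
        for j in range(N_TIMEPOINTS):
            t, p = stats.ttest_ind(a[:, j], b[:, j], equal_var=False)
            diffs.append((j, name, a[:, j].mean() - b[:, j].mean(), t, p))
    # weight loss between consecutive grid points
    wa, wb = grid(sympt, "weight"), grid(asympt, "weight")
    for j in range(1, N_TIMEPOINTS):
        la, lb = wa[:, j - 1] - wa[:, j], wb[:, j - 1] - wb[:, j]
        t, p = stats.ttest_ind(la, lb, equal_var=False)
        diffs.append((j, "weight_loss", la.mean() - lb.mean(), t, p))
    class_differences = pd.DataFrame(
        diffs, columns=["timepoint", "parameter", "mean_diff", "t", "p"])

    corr_rows = []
    for cls, sessions in (("symptomatic", sympt), ("asymptomatic", asympt)):
        w = grid(sessions, "weight")
        for other in ("sbp", "dbp", "hr"):
            v = grid(sessions, other)
            for j in range(N_TIMEPOINTS):
                r, p = stats.pearsonr(w[:, j], v[:, j])
                corr_rows.append((cls, j, f"weight_{other}", r, p))
        sb, db = grid(sessions, "sbp"), grid(sessions, "dbp")
        for j in range(N_TIMEPOINTS):
            r, p = stats.pearsonr(sb[:, j], db[:, j])
            corr_rows.append((cls, j, "sbp_dbp", r, p))
    correlations = pd.DataFrame(
        corr_rows, columns=["class", "timepoint", "pair", "r", "p"])
    return StatReport(class_differences=class_differences, correlations=correlations)


def homogeneous_config(**overrides) -> CohortConfig:
    """A config whose patients share identical means/SDs (null-generator checks)."""
    base = PatientProfile("pt", 60, "M", 0, 75.0, 3.0, 120.0, 8.0, 70.0, 5.0, 70.0, 4.0)
    n_sympt = overrides.pop("n_symptomatic_per_patient", 2)
    profiles = [
        replace(base, patient_id=f"pt{i:02d}", n_symptomatic_sessions=n_sympt)
        for i in range(overrides.pop("n_patients", 10))
    ]
    return CohortConfig(profiles=profiles, **overrides)
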