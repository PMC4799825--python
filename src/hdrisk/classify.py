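"""Dual random-forest training with per-fold oversampling and score fusion.

Each real session is scored under leave-one-out cross-validation: the
held-out session is removed, the remaining symptomatic sessions are
oversampled to balance the fold, two forests are trained (one per stage's
feature/label design), and the held-out row is scored by each.  The fused
score is the arithmetic mean of the two stage scores.  Scores are vote
fractions for the symptomatic class, so higher = more at risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohort import SessionRecord
from .exceptions import InsufficientDataError, TrainingError
from .features import SYMPTOMATIC_LABEL, build_labels, feature_matrix
from .oversample import balance_count, oversample_sessions

logger = logging.getLogger(__name__)


@dataclass
class RFConfig:
    """Random-forest hyperparameters (majority vote over randomized trees)."""

    n_trees: int = 500
    features_per_split: str | int | float = "sqrt"
    min_leaf: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ScoreRecord:
    """Per-session LOOCV output: stage scores, fused score, stage labels."""

    session_id: str
    score_rf1: float
    score_rf2: float
    score_fused: float
    label_rf1: int
    label_rf2: int


class TrainedForest:
    """A fitted forest exposing the symptomatic-class vote fraction."""

    def __init__(self, rf: RandomForestClassifier):
        self._rf = rf
        self._sympt_idx = int(np.flatnonzero(rf.classes_ == SYMPTOMATIC_LABEL)[0])

    def score_symptomatic(self, x: np.ndarray) -> np.ndarray:
        """Fraction of trees voting the symptomatic class, per row."""
        x = np.atleast_2d(np.asarray(x, float))
        votes = np.zeros(x.shape[0])
        for tree in self._rf.estimators_:
            votes += tree.predict(x) == self._sympt_idx
        return votes / len(self._rf.estimators_)


def train_rf(features: np.ndarray, labels: Sequence[int],
             config: RFConfig) -> TrainedForest:
    """Fit a forest on 0/1 labels (0 = symptomatic); deterministic given seed."""
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        min_samples_leaf=config.min_leaf,
        random_state=config.seed,
        n_jobs=1,
    )
    rf.fit(np.asarray(features, float), y)
    return TrainedForest(rf)


def loocv_scores(cohort: Sequence[SessionRecord], rf_config: RFConfig,
                 k: float = 1.0, seed: int = 0) -> list[ScoreRecord]:
    """Leave-one-out scores for every real session.

    Oversampling is redone inside each fold from that fold's training
    symptomatic sessions only, so the held-out session contributes neither
    to forest training nor to the oversampler's moment/correlation
    estimates (asserted per fold).
    """
    if any(s.is_synthetic for s in cohort):
        raise ValueError("LOOCV cohort must contain only real sessions")
    n = len(cohort)
    x1, y1 = feature_matrix(cohort, "RF1")
    x2, y2 = feature_matrix(cohort, "RF2")
    fold_seeds = np.random.SeedSequence(seed).generate_state(3 * n, dtype=np.uint32)

    records: list[ScoreRecord] = []
    for i in range(n):
        held = cohort[i]
        train_sessions = [s for j, s in enumerate(cohort) if j != i]
        sympt = [s for s in train_sessions if s.symptomatic]
        if not sympt or len(sympt) == len(train_sessions):
            warnings.warn(f"fold {i}: training fold lost a class; skipped")
            continue
        try:
            n_new = balance_count(len(train_sessions) - len(sympt), len(sympt))
            synth = oversample_sessions(sympt, n_new, k=k,
                                        seed=int(fold_seeds[3 * i]))
        except (ValueError, InsufficientDataError) as exc:  # degenerate fold
            warnings.warn(f"fold {i}: oversampling failed ({exc}); skipped")
            continue

        # leakage guard: the held-out session is in neither the training
        # set nor the oversampler's estimation sample
        train_ids = {s.session_id for s in train_sessions}
        assert held.session_id not in train_ids
        assert held.session_id not in {s.session_id for s in sympt}
        assert all(s.session_id not in train_ids for s in synth)

        keep = np.arange(n) != i
        xs, _ = feature_matrix(synth, "RF1")
        xs2, _ = feature_matrix(synth, "RF2")
        ys1 = np.full(len(synth), SYMPTOMATIC_LABEL)
        ys2 = np.array([build_labels(s, "RF2") for s in synth], int)
        xt1 = np.vstack([x1[keep], xs]) if len(synth) else x1[keep]
        yt1 = np.concatenate([y1[keep], ys1])
        xt2 = np.vstack([x2[keep], xs2]) if len(synth) else x2[keep]
        yt2 = np.concatenate([y2[keep], ys2])

        if len(np.unique(yt1)) < 2 or len(np.unique(yt2)) < 2:
            warnings.warn(f"fold {i}: a stage's training labels are single-class; skipped")
            continue

        rf1 = train_rf(xt1, yt1, RFConfig(rf_config.n_trees,
                                          rf_config.features_per_split,
                                          rf_config.min_leaf,
                                          int(fold_seeds[3 * i + 1])))
        rf2 = train_rf(xt2, yt2, RFConfig(rf_config.n_trees,
                                          rf_config.features_per_split,
                                          rf_config.min_leaf,
                                          int(fold_seeds[3 * i + 2])))
        s1 = float(rf1.score_symptomatic(x1[i])[0])
        s2 = float(rf2.score_symptomatic(x2[i])[0])
        records.append(ScoreRecord(
            session_id=held.session_id,
            score_rf1=s1,
            score_rf2=s2,
            score_fused=(s1 + s2) / 2.0,
            label_rf1=int(y1[i]),
            label_rf2=int(y2[i]),
        ))
        if (i + 1) % 50 == 0:
            logger.info("LOOCV fold %d/%d done", i + 1, n)
    return records
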