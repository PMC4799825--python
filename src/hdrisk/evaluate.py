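"""ROC/AUC evaluation, Youden cutoff selection, and the noise-scale sweep.

Positive class = symptomatic (label 0); a session is predicted symptomatic
when its score is at or above the cutoff (ties toward alarm).  The ROC is
swept over all distinct score thresholds, the AUC computed by the
trapezoidal rule (equal to the pairwise-ranking probability with ties
counted one half), and its standard error by the Hanley-McNeil closed
form with Q1 = A/(2-A), Q2 = 2A^2/(1+A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import RFConfig, ScoreRecord, loocv_scores
from .cohort import SessionRecord
from .exceptions import EvaluationError
from .features import SYMPTOMATIC_LABEL


@dataclass
class RocResult:
    """ROC sweep plus summary metrics at the Youden-optimal cutoff."""

    thresholds: np.ndarray  # descending distinct scores
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    youden_cutoff: float
    accuracy: float  # percent, at the Youden cutoff
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_pos: int
    n_neg: int


def _split_scores(scores: Sequence[float], labels: Sequence[int]
                  ) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    pos = scores[labels == SYMPTOMATIC_LABEL]
    neg = scores[labels != SYMPTOMATIC_LABEL]
    if len(pos) == 0 or len(neg) == 0:
        raise EvaluationError("both classes must be present")
    return pos, neg


def auc_standard_error(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC."""
    if not 0 <= auc <= 1:
        raise ValueError(f"auc must lie in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class counts must be >= 1")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_and_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Full ROC sweep with AUC, Hanley-McNeil SE and Youden-cutoff metrics."""
    pos, neg = _split_scores(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    sens = np.array([np.mean(pos >= t) for t in thresholds])
    spec = np.array([np.mean(neg < t) for t in thresholds])

    fpr = np.concatenate([[0.0], 1 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    se = auc_standard_error(auc, len(pos), len(neg))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # thresholds descend; first max = higher cutoff
    cutoff = float(thresholds[best])
    acc, sens_pct, spec_pct = performance_at(
        np.concatenate([pos, neg]),
        np.concatenate([np.full(len(pos), SYMPTOMATIC_LABEL),
                        np.full(len(neg), 1 - SYMPTOMATIC_LABEL)]),
        cutoff,
    )
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, auc_se=se, youden_cutoff=cutoff,
        accuracy=acc, sens_at_cutoff=sens_pct, spec_at_cutoff=spec_pct,
        n_pos=len(pos), n_neg=len(neg),
    )


def pairwise_ranking_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force Mann-Whitney AUC: P(pos > neg) + 0.5*P(tie)."""
    pos, neg = _split_scores(scores, labels)
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def compare_aucs(auc1: float, se1: float, auc2: float, se2: float
                 ) -> tuple[float, float]:
    """Two-sided z-test for the difference of two independent AUCs."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    z = (auc1 - auc2) / np.sqrt(se1 ** 2 + se2 ** 2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (ties: higher cutoff)."""
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


def performance_at(scores: Sequence[float], labels: Sequence[int],
                   cutoff: float) -> tuple[float, float, float]:
    """(accuracy%, sensitivity%, specificity%) predicting symptomatic at score >= cutoff."""
    pos, neg = _split_scores(scores, labels)
    tp = np.sum(pos >= cutoff)
    fn = len(pos) - tp
    tn = np.sum(neg < cutoff)
    fp = len(neg) - tn
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (len(pos) + len(neg))
    return float(acc), float(sens), float(spec)


def scores_report(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    """Summarize LOOCV score records: one row per stage plus the fused score."""
    rows = []
    for stage, scores, labels in (
        ("rf1", [r.score_rf1 for r in records], [r.label_rf1 for r in records]),
        ("rf2", [r.score_rf2 for r in records], [r.label_rf2 for r in records]),
        ("fused", [r.score_fused for r in records], [r.label_rf1 for r in records]),
    ):
        roc = roc_and_auc(scores, labels)
        rows.append({
            "stage": stage, "auc": roc.auc, "auc_se": roc.auc_se,
            "cutoff": roc.youden_cutoff, "accuracy": roc.accuracy,
            "sensitivity": roc.sens_at_cutoff, "specificity": roc.spec_at_cutoff,
            "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        })
    return pd.DataFrame(rows)


def bootstrap_auc_se(scores: Sequence[float], labels: Sequence[int],
                     n_boot: int = 500, seed: int = 0) -> float:
    """Bootstrap cross-check for the closed-form AUC standard error."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(scores), len(scores))
        if len(np.unique(labels[idx])) < 2:
            continue
        aucs.append(pairwise_ranking_auc(scores[idx], labels[idx]))
    return float(np.std(aucs, ddof=1))


def k_sweep(cohort: Sequence[SessionRecord], k_values: Sequence[float],
            rf_config: RFConfig, seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """LOOCV AUC per noise scale k, per stage, averaged over seeds.

    Returns a frame with columns ``k, stage, auc, auc_se`` where ``auc`` is
    the mean over seeds and ``auc_se`` the mean Hanley-McNeil SE — the
    inputs to the adjacent-k stability z-test.
    """
    k_values = list(k_values)
    if any(k <= 0 for k in k_values):
        raise ValueError("all k values must be > 0")
    rows = []
    for k in k_values:
        per_stage: dict[str, list[tuple[float, float]]] = {
            "rf1": [], "rf2": [], "fused": []}
        for seed in seeds:
            records = loocv_scores(cohort, rf_config, k=k, seed=seed)
            rep = scores_report(records)
            for _, row in rep.iterrows():
                per_stage[row["stage"]].append((row["auc"], row["auc_se"]))
        for stage, vals in per_stage.items():
            aucs, ses = zip(*vals)
            rows.append({"k": k, "stage": stage,
                         "auc": float(np.mean(aucs)),
                         "auc_se": float(np.mean(ses))})
    return pd.DataFrame(rows)
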