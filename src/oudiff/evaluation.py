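"""Accuracy statistics: pseudo-time inconsistency and lineage PR-AUC.

PIS counts, over all cell pairs ordered by experimental stage, the fraction
whose pseudo-time ordering contradicts the stage ordering; pairs with tied
pseudo-times are excluded from both numerator and denominator. The lineage
score sweeps a threshold over the responsibilities, computes precision and
recall at each threshold, and integrates precision over recall by the
trapezoid rule. Both statistics are invariant under strictly increasing
transforms of their inputs.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .types import DataError, UndefinedScoreError

__all__ = ["pis", "lineage_pr_auc", "lineage_roc_auc", "soft_state_auc", "STATE_SCORES"]


def pis(pseudo_t, experimental_t) -> float:
    """Pseudo-time inconsistency score in [0, 1] (0 = perfectly concordant)."""
    t = np.asarray(pseudo_t, dtype=float)
    te = np.asarray(experimental_t, dtype=float)
    if t.shape != te.shape or t.ndim != 1:
        raise DataError("pseudo-time and experimental-time vectors must match")
    lt_stage = te[:, None] < te[None, :]
    if not np.any(lt_stage):
        raise UndefinedScoreError("need at least one pair with distinct experimental times")
    inconsistent = lt_stage & (t[:, None] > t[None, :])
    consistent = lt_stage & (t[:, None] < t[None, :])
    denom = int(inconsistent.sum() + consistent.sum())
    if denom == 0:
        raise UndefinedScoreError("all pseudo-times tied across stages; PIS undefined")
    return float(inconsistent.sum() / denom)


def _pr_points(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be matching 1-D vectors")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise UndefinedScoreError("both classes must be present")
    thresholds = np.unique(scores)[::-1]
    precisions, recalls = [], []
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & labels).sum())
        precisions.append(tp / int(pred.sum()))
        recalls.append(tp / n_pos)
    return np.asarray(precisions), np.asarray(recalls)


def lineage_pr_auc(gamma_k, labels) -> float:
    """Area under the precision-recall curve for one lineage's responsibilities.

    The curve is anchored at recall 0 with the precision of the highest
    threshold, and the area is the trapezoid integral over recall.
    """
    precisions, recalls = _pr_points(gamma_k, labels)
    recalls = np.concatenate([[0.0], recalls])
    precisions = np.concatenate([[precisions[0]], precisions])
    return float(np.trapezoid(precisions, recalls))


def lineage_roc_auc(gamma_k, labels) -> float:
    """ROC-AUC of the same ranking, reported for reference."""
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise UndefinedScoreError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(gamma_k, dtype=float)))


STATE_SCORES = {"pre": 0.5, "lineageA": 1.0, "lineageB": 0.0}


def soft_state_auc(states, labels, state_scores=None) -> float:
    """PR-AUC for a hard three-state caller scored comparably to soft gamma.

    A pre-bifurcation call counts as belonging to the positive lineage with
    probability 0.5, the positive-lineage call with 1.0, and the other
    lineage with 0.0.
    """
    mapping = dict(STATE_SCORES if state_scores is None else state_scores)
    unknown = sorted({str(s) for s in states if s not in mapping})
    if unknown:
        raise DataError(f"unknown state token(s): {', '.join(unknown)}")
    scores = np.array([mapping[s] for s in states], dtype=float)
    return lineage_pr_auc(scores, labels)
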