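"""Test-set metrics, the attention-focus feature heat map, and embedding
projection.

AUROC is the rank-based (Mann-Whitney) statistic with ties counted half;
AUPRC is the step-wise integral of precision over recall at every
distinct score cut.  The heat map finds, per encounter, the time step
with the greatest attention weight (earliest wins ties; padded columns
excluded) and accumulates the z-scored values of features actually
measured at that step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.stats import rankdata

from ardsight import autodiff as ad
from ardsight.features import N_CONST, TIME_VARYING_FEATURES
from ardsight.model import ModelParams, forward_batch

__all__ = [
    "EvaluationReport",
    "auroc",
    "auprc",
    "confusion_metrics",
    "threshold_for_sensitivity",
    "evaluate_scores",
    "attention_heatmap",
    "embed_project",
]


@dataclass
class EvaluationReport:
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary")
    return labels


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; ties contribute one half."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUROC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Step-wise precision-recall integral over all distinct score cuts."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("at least one positive required for AUPRC")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(1 - labels[order])
    # evaluate only at the last index of each distinct score (the cut)
    distinct = np.flatnonzero(np.diff(sorted_scores) != 0)
    cuts = np.append(distinct, labels.size - 1)
    precision = tp[cuts] / (tp[cuts] + fp[cuts])
    recall = tp[cuts] / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(
    scores, labels, threshold: float
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, PPV, NPV) at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return sens, spec, ppv, npv


def threshold_for_sensitivity(
    scores, labels, target_sensitivity: float = 0.78
) -> float:
    """Largest threshold whose sensitivity reaches the target.

    Intended to be applied on the validation set and transferred to test.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pos_scores = np.sort(scores[labels == 1])[::-1]
    if pos_scores.size == 0:
        raise ValueError("no positives to calibrate a threshold")
    k = int(np.ceil(target_sensitivity * pos_scores.size))
    k = min(max(k, 1), pos_scores.size)
    return float(pos_scores[k - 1])


def evaluate_scores(scores, labels, threshold: float) -> EvaluationReport:
    labels = _check_binary(labels)
    sens, spec, ppv, npv = confusion_metrics(scores, labels, threshold)
    return EvaluationReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        threshold=threshold,
        n_pos=int(labels.sum()),
        n_neg=int(labels.size - labels.sum()),
    )


def attention_heatmap(
    params: ModelParams,
    matrices: np.ndarray,
    batch_size: int = 512,
    log=None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-feature mean z-score at attention-focus steps, plus a min-max
    normalized rendering.

    A feature contributes at an encounter's focus step only where its
    missingness mask is 1.  Features never measured at any focus step map
    to NaN.  Encounters whose kept window is entirely padding are skipped.
    """
    sums = np.zeros(len(TIME_VARYING_FEATURES))
    counts = np.zeros(len(TIME_VARYING_FEATURES))
    with ad.no_grad():
        for lo in range(0, len(matrices), batch_size):
            batch = matrices[lo : lo + batch_size]
            out = forward_batch(batch, params)
            weights = out["attention_weights"].data.T  # (n, T)
            for i, mat in enumerate(batch):
                mask_rows = mat[N_CONST : N_CONST + 2 * len(TIME_VARYING_FEATURES) : 2]
                nonpad = np.flatnonzero(mask_rows.any(axis=0))
                if nonpad.size == 0:
                    if log is not None:
                        log({"skipped": lo + i, "reason": "all-padded"})
                    continue
                w = weights[i][nonpad]
                focus = nonpad[np.argmax(w)]  # argmax returns earliest tie
                for f in range(len(TIME_VARYING_FEATURES)):
                    r = N_CONST + 2 * f
                    if mat[r, focus] == 1.0:
                        sums[f] += mat[r + 1, focus]
                        counts[f] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mean_map = dict(zip(TIME_VARYING_FEATURES, means.tolist()))
    finite = means[np.isfinite(means)]
    if finite.size and finite.max() > finite.min():
        norm = (means - finite.min()) / (finite.max() - finite.min())
    else:
        norm = np.where(np.isfinite(means), 0.5, np.nan)
    norm_map = dict(zip(TIME_VARYING_FEATURES, norm.tolist()))
    return mean_map, norm_map


def embed_project(
    params: ModelParams, matrices: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """Project penultimate embeddings onto their first 2 principal axes."""
    if len(matrices) < 3:
        raise ValueError("need at least 3 encounters to project")
    embs = []
    with ad.no_grad():
        for lo in range(0, len(matrices), batch_size):
            out = forward_batch(matrices[lo : lo + batch_size], params)
            embs.append(out["penultimate"].data)
    X = np.concatenate(embs)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt[:2].T
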