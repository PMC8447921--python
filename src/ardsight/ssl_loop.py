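"""Teacher-student semisupervised loop with confidence-banded pseudolabels.

Each cycle: the current teacher scores the whole unlabeled pool on the
primary (ARDS) outcome; with m the pool-mean probability, samples with
p > 2m become pseudo-positive, p < m pseudo-negative, and the band
[m, 2m] is left unconfident.  A freshly initialized student trains on the
labeled set plus the confident pseudolabeled samples (pseudolabeled
samples contribute ARDS loss only), is fine-tuned on the labeled set, and
becomes the next teacher.  The cycle checkpoint with the best validation
AUROC on the ARDS outcome is returned.

True labels of the unlabeled pool stay behind an access guard that only
the all-data ceiling opens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ardsight.evaluation import auroc
from ardsight.model import ARDS_OUTPUT_INDEX, ModelConfig, ModelParams
from ardsight.training import (
    ArrayDataset,
    GuardedLabels,
    TrainConfig,
    predict_proba,
    train_supervised,
)

__all__ = [
    "UnlabeledPool",
    "PseudolabelResult",
    "SSLState",
    "SSLResult",
    "pseudolabel",
    "ssl_train",
    "train_all_data_ceiling",
]


@dataclass
class UnlabeledPool:
    """Unlabeled feature matrices; true labels sealed behind a guard."""

    ids: list[str]
    matrices: np.ndarray
    guard: GuardedLabels

    def __len__(self) -> int:
        return len(self.ids)

    @staticmethod
    def from_dataset(ds: ArrayDataset) -> "UnlabeledPool":
        return UnlabeledPool(
            ids=list(ds.ids), matrices=ds.matrices, guard=GuardedLabels(ds.labels)
        )


@dataclass
class PseudolabelResult:
    positive: set
    negative: set
    unconfident: set
    mean_prob: float
    positive_idx: np.ndarray = None
    negative_idx: np.ndarray = None
    unconfident_idx: np.ndarray = None


@dataclass
class SSLState:
    """Per-cycle record of the loop."""

    cycle_index: int
    pseudo_positive: set
    pseudo_negative: set
    unconfident: set
    mean_prob: float
    val_auroc: float
    params: ModelParams = None


@dataclass
class SSLResult:
    best_params: ModelParams
    best_cycle: int
    teacher_params: ModelParams
    teacher_val_auroc: float
    history: list[SSLState] = field(default_factory=list)


def pseudolabel(
    teacher: ModelParams, pool: UnlabeledPool, batch_size: int = 512
) -> PseudolabelResult:
    """Partition the pool by the strict m / 2m confidence thresholds."""
    if len(pool) == 0:
        raise ValueError("empty unlabeled pool")
    probs = predict_proba(teacher, pool.matrices, batch_size)[:, ARDS_OUTPUT_INDEX]
    return partition_probabilities(probs, pool.ids)


def partition_probabilities(probs: np.ndarray, ids: list) -> PseudolabelResult:
    """Threshold arithmetic separated out for direct testing."""
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    m = float(probs.mean())
    pos = np.flatnonzero(probs > 2.0 * m)
    neg = np.flatnonzero(probs < m)
    unc = np.flatnonzero((probs >= m) & (probs <= 2.0 * m))
    return PseudolabelResult(
        positive={ids[i] for i in pos},
        negative={ids[i] for i in neg},
        unconfident={ids[i] for i in unc},
        mean_prob=m,
        positive_idx=pos,
        negative_idx=neg,
        unconfident_idx=unc,
    )


def _val_auroc(params: ModelParams, val_set: ArrayDataset, batch_size: int) -> float:
    probs = predict_proba(params, val_set.matrices, batch_size)[:, ARDS_OUTPUT_INDEX]
    return auroc(probs, val_set.labels[:, ARDS_OUTPUT_INDEX])


def _pseudo_dataset(pool: UnlabeledPool, res: PseudolabelResult, n_outputs: int) -> ArrayDataset:
    """Confident pool samples with ARDS-only labels and loss masks."""
    idx = np.concatenate([res.positive_idx, res.negative_idx]).astype(int)
    labels = np.zeros((idx.size, n_outputs))
    labels[: res.positive_idx.size, ARDS_OUTPUT_INDEX] = 1.0
    masks = np.zeros_like(labels)
    masks[:, ARDS_OUTPUT_INDEX] = 1.0  # auxiliary losses masked for pseudolabels
    return ArrayDataset(
        ids=[pool.ids[i] for i in idx],
        matrices=pool.matrices[idx],
        labels=labels,
        masks=masks,
    )


def ssl_train(
    labeled: ArrayDataset,
    pool: UnlabeledPool,
    val_set: ArrayDataset,
    cfg: TrainConfig,
    model_config: ModelConfig,
    n_cycles: int = 4,
    teacher_params: Optional[ModelParams] = None,
    log=None,
) -> SSLResult:
    """Run the full teacher-student loop; see module docstring."""
    if teacher_params is None:
        init = ModelParams(
            ModelConfig(**{**model_config.__dict__, "seed": model_config.seed})
        )
        teacher_params, _ = train_supervised(init, labeled, val_set, cfg, log=log)
    teacher_auroc = _val_auroc(teacher_params, val_set, cfg.batch_size)

    history: list[SSLState] = []
    teacher = teacher_params
    for cycle in range(1, n_cycles + 1):
        res = pseudolabel(teacher, pool, cfg.batch_size)
        n_conf = len(res.positive) + len(res.negative)

        student_init = ModelParams(
            ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + 1000 * cycle})
        )
        if n_conf > 0:
            combined = ArrayDataset.concatenate(
                labeled, _pseudo_dataset(pool, res, model_config.n_outputs)
            )
            student, _ = train_supervised(student_init, combined, val_set, cfg, log=log)
        else:
            if log is not None:
                log({"cycle": cycle, "warning": "no confident pseudolabels; labeled-only"})
            student = student_init
        # fine-tune on the labeled set
        student, _ = train_supervised(student, labeled, val_set, cfg, log=log)

        state = SSLState(
            cycle_index=cycle,
            pseudo_positive=res.positive,
            pseudo_negative=res.negative,
            unconfident=res.unconfident,
            mean_prob=res.mean_prob,
            val_auroc=_val_auroc(student, val_set, cfg.batch_size),
            params=student,
        )
        history.append(state)
        if log is not None:
            log(
                {
                    "cycle": cycle,
                    "n_pos": len(res.positive),
                    "n_neg": len(res.negative),
                    "n_unconfident": len(res.unconfident),
                    "mean_prob": res.mean_prob,
                    "val_auroc": state.val_auroc,
                }
            )
        teacher = student

    if history:
        best = max(history, key=lambda s: s.val_auroc)
        best_params, best_cycle = best.params, best.cycle_index
    else:
        best_params, best_cycle = teacher_params, 0
    return SSLResult(
        best_params=best_params,
        best_cycle=best_cycle,
        teacher_params=teacher_params,
        teacher_val_auroc=teacher_auroc,
        history=history,
    )


def train_all_data_ceiling(
    labeled: ArrayDataset,
    pool: UnlabeledPool,
    val_set: ArrayDataset,
    cfg: TrainConfig,
    model_config: ModelConfig,
    log=None,
) -> ModelParams:
    """Supervised run on labeled + unlabeled with true labels (the ceiling)."""
    with pool.guard.reveal() as guard:
        pool_ds = ArrayDataset(
            ids=list(pool.ids),
            matrices=pool.matrices,
            labels=np.asarray(guard.labels, dtype=float),
        )
    union = ArrayDataset.concatenate(labeled, pool_ds)
    init = ModelParams(
        ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + 777})
    )
    params, _ = train_supervised(init, union, val_set, cfg, log=log)
    return params
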