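"""Cohort splitting and the supervised training loop.

The split reserves whole hospitals as the external test set, then draws a
10% validation set from the remaining pool (round-half-up) and a 30%
labeled set from what is left (floor); the complement is the unlabeled
pool.  With a nontest pool of 25,670 this yields 2567 / 6930 / 16,173.

Training uses Adam starting at lr 0.001, scaling the rate by 0.9 after
the validation loss has risen for 2 consecutive epochs, and keeps the
checkpoint with the lowest validation loss on the primary (ARDS) outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ardsight import autodiff as ad
from ardsight.autodiff import Adam
from ardsight.features import NormalizationStats, build_matrix
from ardsight.labels import Encounter, OutcomeVector, prediction_time
from ardsight.model import ARDS_OUTPUT_INDEX, ModelParams, forward_batch, multitask_loss

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "SplitResult",
    "ArrayDataset",
    "GuardedLabels",
    "split_cohort",
    "train_supervised",
    "predict_proba",
    "dataset_from_cohort",
]


@dataclass
class SplitSpec:
    test_hospitals: frozenset[str] = frozenset()
    validation_fraction: float = 0.10
    labeled_fraction: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for f in (self.validation_fraction, self.labeled_fraction):
            if not 0 < f < 1:
                raise ValueError("split fractions must be in (0, 1)")


@dataclass
class TrainConfig:
    lr0: float = 0.001
    decay_factor: float = 0.9
    patience_epochs: int = 2
    max_epochs: int = 40
    batch_size: int = 256  # 2048 at full production scale; 256 fits desk runs
    early_stop_patience: Optional[int] = None  # epochs without ARDS-val improvement
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.decay_factor < 1:
            raise ValueError("decay_factor must be in (0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class SplitResult:
    test: list
    validation: list
    labeled: list
    unlabeled: list

    def sizes(self) -> dict[str, int]:
        return {
            "test": len(self.test),
            "validation": len(self.validation),
            "labeled": len(self.labeled),
            "unlabeled": len(self.unlabeled),
        }


def _hospital_of(patient) -> str:
    if hasattr(patient, "hospital_id"):
        return patient.hospital_id
    return patient[1]  # (patient_id, hospital_id) tuples


def split_cohort(patients: Sequence, spec: SplitSpec) -> SplitResult:
    """Partition patients into test / validation / labeled / unlabeled.

    Validation size is round-half-up of the fraction of the nontest pool;
    labeled size is the floor of the fraction of the remainder.
    """
    spec.validate()
    patients = list(patients)
    test = [p for p in patients if _hospital_of(p) in spec.test_hospitals]
    nontest = [p for p in patients if _hospital_of(p) not in spec.test_hospitals]
    if not nontest:
        raise ValueError("no non-test patients to split")

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(nontest))
    n_val = int(math.floor(spec.validation_fraction * len(nontest) + 0.5))
    validation = [nontest[i] for i in order[:n_val]]
    rest = [nontest[i] for i in order[n_val:]]
    n_lab = int(math.floor(spec.labeled_fraction * len(rest)))
    labeled = rest[:n_lab]
    unlabeled = rest[n_lab:]
    return SplitResult(test=test, validation=validation, labeled=labeled, unlabeled=unlabeled)


class GuardedLabels:
    """Access guard around the unlabeled pool's true labels.

    Reading ``.labels`` outside a ``reveal()`` context raises; the
    all-data ceiling is the only sanctioned opener.  ``access_count``
    records sanctioned reads so tests can assert the guard stayed shut.
    """

    def __init__(self, labels: np.ndarray):
        self._labels = np.asarray(labels)
        self._open = False
        self.access_count = 0

    @property
    def labels(self) -> np.ndarray:
        if not self._open:
            raise PermissionError("unlabeled-pool true labels are sealed")
        self.access_count += 1
        return self._labels

    def reveal(self):
        guard = self

        class _Reveal:
            def __enter__(self):
                guard._open = True
                return guard

            def __exit__(self, *exc):
                guard._open = False
                return False

        return _Reveal()


@dataclass
class ArrayDataset:
    """Feature matrices with per-sample outcome labels and loss masks."""

    ids: list[str]
    matrices: np.ndarray  # (n, rows, steps)
    labels: np.ndarray  # (n, 7) in {0,1}
    masks: np.ndarray = None  # (n, 7); 1 = outcome contributes to the loss

    def __post_init__(self):
        if self.masks is None:
            self.masks = np.ones_like(self.labels, dtype=float)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(
            ids=[self.ids[i] for i in idx],
            matrices=self.matrices[idx],
            labels=self.labels[idx],
            masks=self.masks[idx],
        )

    @staticmethod
    def concatenate(a: "ArrayDataset", b: "ArrayDataset") -> "ArrayDataset":
        return ArrayDataset(
            ids=a.ids + b.ids,
            matrices=np.concatenate([a.matrices, b.matrices]),
            labels=np.concatenate([a.labels, b.labels]),
            masks=np.concatenate([a.masks, b.masks]),
        )


def dataset_from_cohort(
    labeled_pairs: Iterable[tuple[Encounter, OutcomeVector]],
    stats: NormalizationStats,
) -> ArrayDataset:
    """Build a dataset from labeled encounters that have a prediction time."""
    ids, mats, labels = [], [], []
    for enc, out in labeled_pairs:
        if prediction_time(enc) is None:
            continue
        ids.append(enc.patient_id)
        mats.append(build_matrix(enc, stats))
        labels.append(out.as_array())
    if not mats:
        raise ValueError("no encounters with a prediction time")
    return ArrayDataset(
        ids=ids,
        matrices=np.stack(mats),
        labels=np.asarray(labels, dtype=float),
    )


def predict_proba(
    params: ModelParams, matrices: np.ndarray, batch_size: int = 512
) -> np.ndarray:
    """Sigmoid outcome probabilities, (n, 7), without gradient tracking."""
    probs = []
    with ad.no_grad():
        for lo in range(0, len(matrices), batch_size):
            out = forward_batch(matrices[lo : lo + batch_size], params)
            probs.append(1.0 / (1.0 + np.exp(-out["logits"].data)))
    return np.concatenate(probs) if probs else np.zeros((0, params.config.n_outputs))


def _dataset_loss(
    params: ModelParams, ds: ArrayDataset, batch_size: int
) -> tuple[float, float]:
    """(multitask loss, ARDS-only loss) over a dataset, gradient-free."""
    total, total_n = 0.0, 0.0
    ards_total, ards_n = 0.0, 0.0
    with ad.no_grad():
        for lo in range(0, len(ds), batch_size):
            sl = slice(lo, lo + batch_size)
            out = forward_batch(ds.matrices[sl], params)
            logits = out["logits"]
            m = ds.masks[sl]
            loss = multitask_loss(logits, ds.labels[sl], m)
            total += loss.data * m.sum()
            total_n += m.sum()
            ards_mask = np.zeros_like(m)
            ards_mask[:, ARDS_OUTPUT_INDEX] = m[:, ARDS_OUTPUT_INDEX]
            if ards_mask.sum():
                aloss = multitask_loss(logits, ds.labels[sl], ards_mask)
                ards_total += aloss.data * ards_mask.sum()
                ards_n += ards_mask.sum()
    return total / max(total_n, 1.0), ards_total / max(ards_n, 1.0)


def train_supervised(
    init_params: ModelParams,
    train_set: ArrayDataset,
    val_set: ArrayDataset,
    cfg: TrainConfig,
    log=None,
) -> tuple[ModelParams, list[dict]]:
    """Adam training with decay scheduling and best-checkpoint selection.

    The scheduler watches the multitask validation loss; the returned
    checkpoint minimizes the ARDS-only validation loss.  The per-epoch
    trace records train loss, both validation losses, and the lr.
    """
    cfg.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")

    params = init_params.copy()
    opt = Adam(params.parameters(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed)

    trace: list[dict] = []
    best_val_ards = np.inf
    best_params = params.copy()
    prev_val = np.inf
    increase_streak = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            out = forward_batch(train_set.matrices[idx], params)
            loss = multitask_loss(out["logits"], train_set.labels[idx], train_set.masks[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1

        val_loss, val_ards = _dataset_loss(params, val_set, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        if val_loss > prev_val:
            increase_streak += 1
        else:
            increase_streak = 0
        if increase_streak >= cfg.patience_epochs:
            opt.lr *= cfg.decay_factor
            increase_streak = 0
        prev_val = val_loss

        if val_ards < best_val_ards:
            best_val_ards = val_ards
            best_params = params.copy()

        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_loss": float(val_loss),
            "val_ards_loss": float(val_ards),
            "lr": opt.lr,
        }
        trace.append(record)
        if log is not None:
            log(record)

        # "train until validation convergence": optional early exit once the
        # checkpoint metric has stalled; the best checkpoint is kept anyway
        if cfg.early_stop_patience is not None:
            best_epoch = min(range(len(trace)), key=lambda i: trace[i]["val_ards_loss"])
            if epoch > best_epoch and epoch - best_epoch >= max(cfg.early_stop_patience, 1):
                break

    return best_params, trace
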