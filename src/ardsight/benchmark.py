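"""Desk-scale semisupervised benchmark on the synthetic cohort.

Builds a cohort with a fixed prevalence and signal strength, carves out
labeled / unlabeled / validation / test sets of requested sizes, then
trains the teacher, the SSL loop, and the all-data ceiling, reporting
test AUROC for each.  Used by the acceptance suite to check the ordering
teacher <= best-SSL <= all-data; training runs in float32 with a reduced
hidden size to stay inside a single-CPU time budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ardsight import autodiff as ad
from ardsight.evaluation import auroc
from ardsight.features import fit_stats
from ardsight.labels import inclusion_filter, label_cohort
from ardsight.model import ARDS_OUTPUT_INDEX, ModelConfig
from ardsight.ssl_loop import UnlabeledPool, ssl_train, train_all_data_ceiling
from ardsight.synth_cohort import CohortConfig, generate_cohort
from ardsight.training import ArrayDataset, TrainConfig, dataset_from_cohort, predict_proba

__all__ = ["BenchmarkResult", "run_ssl_benchmark"]


@dataclass
class BenchmarkResult:
    teacher_auroc: float
    ssl_auroc: float
    all_data_auroc: float
    best_cycle: int
    teacher_val_auroc: float
    ssl_val_auroc: float


def _take(ds: ArrayDataset, idx: np.ndarray) -> ArrayDataset:
    return ds.subset(idx)


def run_ssl_benchmark(
    seed: int,
    n_labeled: int = 1500,
    n_unlabeled: int = 4000,
    n_val: int = 500,
    n_test: int = 1000,
    prevalence: float = 0.05,
    signal_strength: float = 1.0,
    hidden_size: int = 32,
    max_epochs: int = 15,
    n_cycles: int = 4,
    batch_size: int = 128,
    early_stop_patience: int = 3,
    dtype=np.float32,
) -> BenchmarkResult:
    n_needed = n_labeled + n_unlabeled + n_val + n_test
    cohort_cfg = CohortConfig(
        # oversample so the inclusion filter still leaves enough encounters
        n_patients=int(np.ceil(n_needed / 0.55)),
        ards_prevalence=prevalence,
        deterioration_signal_strength=signal_strength,
        seed=seed,
    )
    encounters = generate_cohort(cohort_cfg)
    labeled_pairs = [
        (e, o) for e, o in label_cohort(encounters) if inclusion_filter(e)
    ]
    if len(labeled_pairs) < n_needed:
        raise RuntimeError(
            f"only {len(labeled_pairs)} included encounters for {n_needed} requested"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled_pairs))
    cuts = np.cumsum([n_test, n_val, n_labeled, n_unlabeled])
    test_p = [labeled_pairs[i] for i in order[: cuts[0]]]
    val_p = [labeled_pairs[i] for i in order[cuts[0] : cuts[1]]]
    lab_p = [labeled_pairs[i] for i in order[cuts[1] : cuts[2]]]
    unl_p = [labeled_pairs[i] for i in order[cuts[2] : cuts[3]]]

    stats = fit_stats([e for e, _ in lab_p])
    with ad.use_dtype(dtype):
        ds_lab = dataset_from_cohort(lab_p, stats)
        ds_val = dataset_from_cohort(val_p, stats)
        ds_test = dataset_from_cohort(test_p, stats)
        pool = UnlabeledPool.from_dataset(dataset_from_cohort(unl_p, stats))

        train_cfg = TrainConfig(
            max_epochs=max_epochs,
            batch_size=batch_size,
            early_stop_patience=early_stop_patience,
            seed=seed,
        )
        model_cfg = ModelConfig(hidden_size=hidden_size, seed=seed)

        result = ssl_train(ds_lab, pool, ds_val, train_cfg, model_cfg, n_cycles=n_cycles)
        ceiling = train_all_data_ceiling(ds_lab, pool, ds_val, train_cfg, model_cfg)

        y_test = ds_test.labels[:, ARDS_OUTPUT_INDEX]

        def test_auroc(params) -> float:
            scores = predict_proba(params, ds_test.matrices, batch_size)[:, ARDS_OUTPUT_INDEX]
            return auroc(scores, y_test)

        best_state = max(result.history, key=lambda s: s.val_auroc) if result.history else None
        return BenchmarkResult(
            teacher_auroc=test_auroc(result.teacher_params),
            ssl_auroc=test_auroc(result.best_params),
            all_data_auroc=test_auroc(ceiling),
            best_cycle=result.best_cycle,
            teacher_val_auroc=result.teacher_val_auroc,
            ssl_val_auroc=best_state.val_auroc if best_state else result.teacher_val_auroc,
        )
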