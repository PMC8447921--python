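# ardsight

Semisupervised early-warning pipeline for acute respiratory distress
syndrome (ARDS) from irregular EHR-style time series, with a synthetic
cohort generator so every stage runs without patient data.

The pipeline:

1. **simulate** — a seedable generator emits encounters in which a latent
   deterioration process drives an SpO2 decline below 97% (the prediction
   time), optionally below 92% or a PaO2/FiO2 ratio < 300 (respiratory
   failure), followed by lagged ARDS ICD coding, six correlated auxiliary
   outcomes, and pre-admission ICD history.
2. **label** — gold-standard labeling: prediction time (first SpO2 < 97),
   respiratory-failure onset (SpO2 < 92 or PaO2/FiO2 < 300), ARDS ICD
   onset with a 1000-hour pre-admission novelty rule, and 7 binary
   outcomes per encounter.
3. **features** — a fixed 49 x 32 matrix per encounter: 6 constant rows,
   (mask, value) row pairs for 21 time-varying features, and a z-scored
   inter-step-minutes row; at most 32 update steps before the prediction
   time, left-padded with zeros.
4. **model** — an attention-GRU classifier: a learned normalization layer
   `a * (v - mu) / (sigma + eps) + b`, a 2-layer GRU (64 hidden units), a
   soft-attention scorer `K . tanh(A . prelu(B . n([l, h])))`, a context
   vector, and a 2-layer head producing 7 logits through a 64-d
   penultimate embedding. Implemented on a small numpy reverse-mode
   autodiff engine (no GPU frameworks required); gradients are verified
   against finite differences in the test suite.
5. **train / ssl** — by-hospital test hold-out, 10% validation, 30/70
   labeled/unlabeled split; Adam (lr 0.001) with a x0.9 decay after two
   consecutive validation-loss increases and best-checkpoint selection on
   the ARDS outcome; then a teacher–student loop: pool-mean confidence
   thresholds (p > 2m positive, p < m negative, otherwise unconfident),
   a freshly initialized student per cycle trained on labeled +
   confident pseudolabels (ARDS loss only for pseudolabels), fine-tuned
   on the labeled set, best cycle selected by validation AUROC. The
   unlabeled pool's true labels sit behind an access guard that only the
   all-data ceiling may open.
6. **evaluate** — AUROC (rank-based), AUPRC (step-wise PR integral),
   sensitivity/specificity/PPV/NPV at a validation-calibrated threshold,
   the attention-focus feature heat map, and 2-D PCA of the penultimate
   embeddings.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a 5-seed semisupervised benchmark
(`tests/test_acceptance.py::test_criterion_6_ssl_ordering_benchmark`)
that trains 15 small models and takes ~10–13 minutes on one CPU; the
rest of the suite runs in about two minutes.

## CLI

All commands read one YAML config (see `ardsight.io.RunConfig`); `--seed`
overrides every stage seed at once.

```sh
ardsight simulate --config config.yaml          # write observations/events CSVs
ardsight label    --config config.yaml          # write labels.csv
ardsight split    --config config.yaml          # write split.json
ardsight run-all  --config config.yaml          # full pipeline + report.json
ardsight train    --config config.yaml          # teacher on the labeled split
ardsight ssl-train --config config.yaml --cycles 4
ardsight train-ceiling --config config.yaml     # all-data ceiling model
ardsight evaluate --config config.yaml --checkpoint run/ssl_best.npz
ardsight heatmap  --config config.yaml --checkpoint run/ssl_best.npz
ardsight project  --config config.yaml --checkpoint run/ssl_best.npz
```

Example config:

```yaml
output_dir: runs/demo
seed: 7
cohort:
  n_patients: 2000
  ards_prevalence: 0.05
  deterioration_signal_strength: 1.0
split:
  test_hospitals: [H0, H1, H2]
train:
  max_epochs: 15
  batch_size: 128
ssl_cycles: 4
```

## Data formats

- `observations.csv`: `patient_id, timestamp (ISO 8601), feature_name, value`
- `events.csv`: `patient_id, timestamp, event_type, code` with
  `event_type` in {icd, antibiotics, supplemental_o2, mech_vent,
  admission, discharge}; the admission event's `code` carries the
  hospital id.
- `labels.csv`: patient id, 7 boolean outcome columns, 3 timestamp columns.
- Feature-matrix row layout: `src/ardsight/feature_layout.yaml`;
  matrices can be persisted to HDF5 with per-patient keys.
- Checkpoints: single-file `.npz` with an embedded config hash.
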