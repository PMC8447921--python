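"""CSV readers/writers, run configuration, and pipeline orchestration.

On disk, a cohort is two CSV files:

- ``observations.csv``: patient_id, timestamp (ISO 8601), feature_name, value
- ``events.csv``: patient_id, timestamp, event_type, code

Timestamps are absolute; every encounter must have an ``admission`` event
(whose ``code`` carries the hospital id) and a ``discharge`` event.
Internally all times are float hours relative to admission; pre-admission
ICD history keeps negative times.  Demographics travel as pseudo
observations (``age``, ``male``, ``female``) stamped at admission.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ardsight.features import fit_stats
from ardsight.labels import (
    OUTCOME_NAMES,
    Encounter,
    Event,
    Observation,
    inclusion_filter,
    label_cohort,
)
from ardsight.model import ModelConfig, save_checkpoint
from ardsight.ssl_loop import UnlabeledPool, ssl_train, train_all_data_ceiling
from ardsight.synth_cohort import CohortConfig, generate_cohort
from ardsight.training import (
    ArrayDataset,
    SplitSpec,
    TrainConfig,
    dataset_from_cohort,
    split_cohort,
)

__all__ = [
    "RunConfig",
    "EPOCH",
    "write_cohort",
    "read_cohort",
    "write_labels",
    "PreparedData",
    "prepare_datasets",
    "run_pipeline",
]

EPOCH = datetime(2019, 5, 1)


def _to_timestamp(abs_hours: float) -> str:
    return (EPOCH + timedelta(hours=abs_hours)).isoformat()


def _log(stage: str, **kv) -> None:
    print(json.dumps({"stage": stage, "time": time.time(), **kv}), file=sys.stderr)


def write_cohort(encounters: list[Encounter], obs_path, events_path) -> None:
    obs_rows = []
    ev_rows = []
    for enc in encounters:
        t0 = enc.admission_time
        if enc.age is not None:
            obs_rows.append((enc.patient_id, _to_timestamp(t0), "age", enc.age))
        if enc.sex is not None:
            obs_rows.append(
                (enc.patient_id, _to_timestamp(t0), "male", 1.0 if enc.sex == "male" else 0.0)
            )
            obs_rows.append(
                (enc.patient_id, _to_timestamp(t0), "female", 1.0 if enc.sex == "female" else 0.0)
            )
        for o in enc.observations:
            obs_rows.append((enc.patient_id, _to_timestamp(t0 + o.time), o.feature, o.value))
        ev_rows.append((enc.patient_id, _to_timestamp(t0), "admission", enc.hospital_id))
        ev_rows.append(
            (enc.patient_id, _to_timestamp(t0 + enc.discharge_time), "discharge", "")
        )
        for e in enc.events:
            ev_rows.append((enc.patient_id, _to_timestamp(t0 + e.time), e.event_type, e.code))
    pd.DataFrame(
        obs_rows, columns=["patient_id", "timestamp", "feature_name", "value"]
    ).to_csv(obs_path, index=False)
    pd.DataFrame(
        ev_rows, columns=["patient_id", "timestamp", "event_type", "code"]
    ).to_csv(events_path, index=False)


def _parse_times(df: pd.DataFrame, path) -> pd.Series:
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} at data row {row + 1}"
        )
    return ts


def read_cohort(obs_path, events_path) -> list[Encounter]:
    """Read a cohort from the two-CSV schema; see module docstring."""
    obs_df = pd.read_csv(obs_path)
    ev_df = pd.read_csv(events_path)
    expected_obs = ["patient_id", "timestamp", "feature_name", "value"]
    expected_ev = ["patient_id", "timestamp", "event_type", "code"]
    if list(obs_df.columns) != expected_obs:
        raise ValueError(f"{obs_path}: unexpected columns {list(obs_df.columns)}")
    if list(ev_df.columns) != expected_ev:
        raise ValueError(f"{events_path}: unexpected columns {list(ev_df.columns)}")

    obs_df = obs_df.assign(ts_parsed=_parse_times(obs_df, obs_path))
    ev_df = ev_df.assign(ts_parsed=_parse_times(ev_df, events_path))
    ev_df["code"] = ev_df["code"].fillna("").astype(str)

    encounters = []
    obs_groups = dict(tuple(obs_df.groupby("patient_id", sort=False)))
    for pid, ev_g in ev_df.groupby("patient_id", sort=False):
        adm = ev_g[ev_g["event_type"] == "admission"]
        if adm.empty:
            raise ValueError(f"{events_path}: patient {pid} has no admission event")
        adm_ts = adm["ts_parsed"].iloc[0]
        hospital = str(adm["code"].iloc[0]) or "H0"
        dis = ev_g[ev_g["event_type"] == "discharge"]
        dis_ts = dis["ts_parsed"].iloc[0] if not dis.empty else ev_g["ts_parsed"].max()

        def rel_hours(ts) -> float:
            return round((ts - adm_ts).total_seconds() / 3600.0, 6)

        age: Optional[float] = None
        sex: Optional[str] = None
        observations = []
        g = obs_groups.get(pid)
        if g is not None:
            for row in g.itertuples(index=False):
                feat = row.feature_name
                if feat == "age":
                    age = float(row.value)
                elif feat == "male":
                    if row.value == 1.0:
                        sex = "male"
                elif feat == "female":
                    if row.value == 1.0:
                        sex = "female"
                else:
                    observations.append(
                        Observation(feat, float(row.value), rel_hours(row.ts_parsed))
                    )
        events = [
            Event(row.event_type, str(row.code), rel_hours(row.ts_parsed))
            for row in ev_g.itertuples(index=False)
            if row.event_type not in ("admission", "discharge")
        ]
        observations.sort(key=lambda o: (o.time, o.feature))
        events.sort(key=lambda e: (e.time, e.event_type, e.code))
        encounters.append(
            Encounter(
                patient_id=str(pid),
                admission_time=round((adm_ts - pd.Timestamp(EPOCH)).total_seconds() / 3600.0, 6),
                discharge_time=rel_hours(dis_ts),
                observations=observations,
                events=events,
                hospital_id=hospital,
                age=age,
                sex=sex,
            )
        )
    return encounters


def write_labels(labeled_pairs, path) -> None:
    rows = []
    for enc, out in labeled_pairs:
        row = {"patient_id": enc.patient_id}
        for name in OUTCOME_NAMES:
            row[name] = int(getattr(out, name))
        for name in ("prediction_time", "resp_failure_onset", "ards_icd_onset"):
            row[name] = getattr(out, name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Single-YAML configuration for the end-to-end pipeline."""

    output_dir: str = "runs/default"
    observations_path: Optional[str] = None  # default: generated under output_dir
    events_path: Optional[str] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    split: SplitSpec = field(default_factory=lambda: SplitSpec(test_hospitals=frozenset({"H0", "H1", "H2"})))
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ssl_cycles: int = 4
    target_sensitivity: float = 0.78
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        cfg = cls()
        for key in ("output_dir", "observations_path", "events_path", "ssl_cycles",
                    "target_sensitivity", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "cohort" in raw:
            cfg.cohort = CohortConfig(**raw["cohort"])
        if "split" in raw:
            spl = dict(raw["split"])
            if "test_hospitals" in spl:
                spl["test_hospitals"] = frozenset(spl["test_hospitals"])
            cfg.split = SplitSpec(**spl)
        if "train" in raw:
            cfg.train = TrainConfig(**raw["train"])
        if "model" in raw:
            cfg.model = ModelConfig(**raw["model"])
        # one seed drives every stage unless overridden
        cfg.cohort.seed = raw.get("cohort", {}).get("seed", cfg.seed)
        cfg.split.seed = raw.get("split", {}).get("seed", cfg.seed)
        cfg.train.seed = raw.get("train", {}).get("seed", cfg.seed)
        cfg.model.seed = raw.get("model", {}).get("seed", cfg.seed)
        return cfg


@dataclass
class PreparedData:
    """Datasets and artifacts shared by the training/evaluation stages."""

    labeled: ArrayDataset
    validation: ArrayDataset
    test: ArrayDataset
    pool: UnlabeledPool
    stats: object


def prepare_datasets(config: RunConfig, resume: bool = True) -> PreparedData:
    """simulate -> label -> split, then build feature matrices per split."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs_path = Path(config.observations_path or out / "observations.csv")
    ev_path = Path(config.events_path or out / "events.csv")

    if not (resume and obs_path.exists() and ev_path.exists()):
        _log("simulate", n=config.cohort.n_patients, seed=config.cohort.seed)
        write_cohort(generate_cohort(config.cohort), obs_path, ev_path)
    encounters = read_cohort(obs_path, ev_path)

    labels_path = out / "labels.csv"
    labeled = label_cohort(encounters)
    if not (resume and labels_path.exists()):
        _log("label", n=len(labeled))
        write_labels(labeled, labels_path)

    included = [(e, o) for e, o in labeled if inclusion_filter(e)]
    split = split_cohort([e for e, _ in included], config.split)
    (out / "split.json").write_text(
        json.dumps({k: sorted(p.patient_id for p in v) for k, v in
                    {"test": split.test, "validation": split.validation,
                     "labeled": split.labeled, "unlabeled": split.unlabeled}.items()})
    )
    _log("split", **split.sizes())

    out_by_id = {e.patient_id: o for e, o in included}
    enc_by_id = {e.patient_id: e for e, _ in included}
    stats = fit_stats([enc_by_id[p.patient_id] for p in split.labeled])

    def make_ds(patients) -> ArrayDataset:
        pairs = [(enc_by_id[p.patient_id], out_by_id[p.patient_id]) for p in patients]
        return dataset_from_cohort(pairs, stats)

    return PreparedData(
        labeled=make_ds(split.labeled),
        validation=make_ds(split.validation),
        test=make_ds(split.test),
        pool=UnlabeledPool.from_dataset(make_ds(split.unlabeled)),
        stats=stats,
    )


def run_pipeline(config: RunConfig, resume: bool = True) -> dict:
    """simulate -> label -> split -> teacher -> ssl -> ceiling -> evaluate.

    Each stage writes its artifacts under ``config.output_dir`` and is
    skipped on resume when they already exist.  Returns the final report.
    """
    from ardsight.evaluation import evaluate_scores, threshold_for_sensitivity
    from ardsight.model import ARDS_OUTPUT_INDEX
    from ardsight.training import predict_proba

    out = Path(config.output_dir)
    data = prepare_datasets(config, resume=resume)
    ds_labeled, ds_val, ds_test, pool = (
        data.labeled, data.validation, data.test, data.pool,
    )

    _log("ssl_train", cycles=config.ssl_cycles)
    result = ssl_train(
        ds_labeled, pool, ds_val, config.train, config.model,
        n_cycles=config.ssl_cycles, log=lambda r: _log("ssl", **{k: v for k, v in r.items() if not isinstance(v, set)}),
    )
    save_checkpoint(out / "teacher.npz", result.teacher_params)
    save_checkpoint(out / "ssl_best.npz", result.best_params)
    (out / "ssl_cycles.json").write_text(
        json.dumps(
            [
                {
                    "cycle": s.cycle_index,
                    "n_pseudo_positive": len(s.pseudo_positive),
                    "n_pseudo_negative": len(s.pseudo_negative),
                    "n_unconfident": len(s.unconfident),
                    "threshold_m": s.mean_prob,
                    "threshold_2m": 2 * s.mean_prob,
                    "val_auroc": s.val_auroc,
                }
                for s in result.history
            ],
            indent=2,
        )
    )

    _log("ceiling")
    ceiling = train_all_data_ceiling(ds_labeled, pool, ds_val, config.train, config.model)
    save_checkpoint(out / "all_data.npz", ceiling)

    report = {}
    for name, params in (
        ("teacher", result.teacher_params),
        ("ssl", result.best_params),
        ("all_data", ceiling),
    ):
        val_scores = predict_proba(params, ds_val.matrices)[:, ARDS_OUTPUT_INDEX]
        thr = threshold_for_sensitivity(
            val_scores, ds_val.labels[:, ARDS_OUTPUT_INDEX], config.target_sensitivity
        )
        test_scores = predict_proba(params, ds_test.matrices)[:, ARDS_OUTPUT_INDEX]
        rep = evaluate_scores(test_scores, ds_test.labels[:, ARDS_OUTPUT_INDEX], thr)
        report[name] = rep.as_dict()
        _log("evaluate", model=name, auroc=rep.auroc, auprc=rep.auprc)
    report["best_ssl_cycle"] = result.best_cycle
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
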