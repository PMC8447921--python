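"""Fixed-layout feature-matrix construction for the sequence model.

Layout (49 rows x 32 time-step columns):

- rows 0-5: constants -- z-scored age, male, female, antibiotics before
  prediction time, supplemental O2 before prediction time, heart-failure
  history;
- rows 6-47: for each of the 21 time-varying features, a (mask, value)
  row pair -- mask 1 when the feature was updated at that step, value the
  z-scored measurement (0 where the mask is 0);
- row 48: minutes elapsed since the previous kept step, z-scored (0 for
  the first kept step and for zero-padded columns).

Columns are update steps: distinct observation times at or before the
prediction time.  At most 32 steps are kept (the most recent); shorter
sequences are left-padded with all-zero columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ardsight.labels import Encounter, heart_failure_history, prediction_time

__all__ = [
    "TIME_VARYING_FEATURES",
    "CONSTANT_FEATURES",
    "N_ROWS",
    "N_STEPS",
    "NormalizationStats",
    "fit_stats",
    "build_matrix",
    "build_matrices",
    "save_matrices",
    "load_matrices",
]

#: The 21 time-varying model inputs, in row order.
TIME_VARYING_FEATURES = (
    "SysBP",
    "DiasBP",
    "HR",
    "Temp",
    "RespRate",
    "SpO2",
    "creatinine",
    "BUN",
    "bilirubin",
    "glucose",
    "INR",
    "WBC",
    "RBC",
    "platelets",
    "neutrophil_pct",
    "lymphocyte_pct",
    "monocyte_pct",
    "hematocrit",
    "lactate",
    "AST",
    "ALT",
)

CONSTANT_FEATURES = (
    "age",
    "male",
    "female",
    "antibiotics_before_prediction",
    "supplemental_o2_before_prediction",
    "heart_failure_history",
)

N_STEPS = 32
N_CONST = len(CONSTANT_FEATURES)
N_ROWS = N_CONST + 2 * len(TIME_VARYING_FEATURES) + 1  # 6 + 42 + 1 = 49

SD_FLOOR = 1e-6


@dataclass
class NormalizationStats:
    """Training-set mean/SD per feature, plus age and inter-step minutes."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    age_mean: float = 0.0
    age_sd: float = 1.0
    delta_minutes_mean: float = 0.0
    delta_minutes_sd: float = 1.0

    @classmethod
    def identity(cls) -> "NormalizationStats":
        """Stats that leave values unchanged (mean 0, sd 1); test helper."""
        s = cls()
        s.means = {f: 0.0 for f in TIME_VARYING_FEATURES}
        s.sds = {f: 1.0 for f in TIME_VARYING_FEATURES}
        return s

    def z(self, feature: str, value: float) -> float:
        return (value - self.means[feature]) / self.sds[feature]


def _floored_sd(x: np.ndarray) -> float:
    if x.size < 2:
        return SD_FLOOR
    return max(float(np.std(x, ddof=1)), SD_FLOOR)


def _update_times(enc: Encounter, t_pred: float) -> np.ndarray:
    times = sorted(
        {
            o.time
            for o in enc.observations
            if o.feature in _FEATURE_SET and 0 <= o.time <= t_pred
        }
    )
    return np.asarray(times, dtype=float)


_FEATURE_SET = frozenset(TIME_VARYING_FEATURES)


def fit_stats(training_encounters: Iterable[Encounter]) -> NormalizationStats:
    """Estimate per-feature mean/SD over pre-prediction-time observations.

    Pools all observations at or before each training encounter's
    prediction time; encounters without a prediction time contribute
    nothing.  Inter-step gaps (in minutes) are pooled across encounters.
    Degenerate SDs are floored at ``SD_FLOOR``.
    """
    encounters = list(training_encounters)
    if not encounters:
        raise ValueError("empty training set")

    pooled: dict[str, list[float]] = {f: [] for f in TIME_VARYING_FEATURES}
    ages: list[float] = []
    deltas: list[float] = []
    for enc in encounters:
        t_pred = prediction_time(enc)
        if t_pred is None:
            continue
        if enc.age is not None:
            ages.append(float(enc.age))
        for o in enc.observations:
            if o.feature in _FEATURE_SET and 0 <= o.time <= t_pred:
                pooled[o.feature].append(o.value)
        times = _update_times(enc, t_pred)
        if times.size >= 2:
            deltas.extend((np.diff(times) * 60.0).tolist())

    if not any(pooled.values()):
        raise ValueError("no pre-prediction-time observations in training set")

    stats = NormalizationStats()
    for f in TIME_VARYING_FEATURES:
        arr = np.asarray(pooled[f], dtype=float)
        stats.means[f] = float(arr.mean()) if arr.size else 0.0
        stats.sds[f] = _floored_sd(arr)
    age_arr = np.asarray(ages, dtype=float)
    stats.age_mean = float(age_arr.mean()) if age_arr.size else 0.0
    stats.age_sd = _floored_sd(age_arr)
    delta_arr = np.asarray(deltas, dtype=float)
    stats.delta_minutes_mean = float(delta_arr.mean()) if delta_arr.size else 0.0
    stats.delta_minutes_sd = _floored_sd(delta_arr)
    return stats


def build_matrix(enc: Encounter, stats: NormalizationStats) -> np.ndarray:
    """Build the 49 x 32 feature matrix for one encounter.

    Raises ``ValueError`` if the encounter has no prediction time or an
    observation carries an unknown feature name (PaO2/FiO2, used only for
    labeling, are silently ignored).
    """
    t_pred = prediction_time(enc)
    if t_pred is None:
        raise ValueError(f"encounter {enc.patient_id}: no prediction time")
    for o in enc.observations:
        if o.feature not in _FEATURE_SET and o.feature not in ("PaO2", "FiO2"):
            raise ValueError(
                f"encounter {enc.patient_id}: unknown feature {o.feature!r}"
            )

    times = _update_times(enc, t_pred)
    kept = times[-N_STEPS:] if times.size > N_STEPS else times
    n_kept = kept.size
    pad = N_STEPS - n_kept

    m = np.zeros((N_ROWS, N_STEPS), dtype=float)

    # constants
    if enc.age is not None:
        m[0, :] = (enc.age - stats.age_mean) / stats.age_sd
    m[1, :] = 1.0 if enc.sex == "male" else 0.0
    m[2, :] = 1.0 if enc.sex == "female" else 0.0
    m[3, :] = float(
        any(e.event_type == "antibiotics" and e.time <= t_pred for e in enc.events)
    )
    m[4, :] = float(
        any(e.event_type == "supplemental_o2" and e.time <= t_pred for e in enc.events)
    )
    m[5, :] = float(heart_failure_history(enc))

    col_of = {t: pad + i for i, t in enumerate(kept)}
    row_of = {f: N_CONST + 2 * i for i, f in enumerate(TIME_VARYING_FEATURES)}
    for o in sorted(enc.observations, key=lambda o: o.time):
        if o.feature not in _FEATURE_SET:
            continue
        col = col_of.get(o.time)
        if col is None:
            continue
        r = row_of[o.feature]
        m[r, col] = 1.0  # mask; later same-time obs of same feature overwrite
        m[r + 1, col] = stats.z(o.feature, o.value)

    # time-delta row: z-scored minutes since previous kept step
    if n_kept >= 2:
        gaps = np.diff(kept) * 60.0
        m[N_ROWS - 1, pad + 1 :] = (gaps - stats.delta_minutes_mean) / stats.delta_minutes_sd
    # first kept step and padded columns stay 0

    # padded columns are all-zero including constants, per the zero-padding rule
    if pad:
        m[:, :pad] = 0.0
    return m


def build_matrices(
    encounters: Iterable[Encounter], stats: NormalizationStats
) -> tuple[list[str], np.ndarray]:
    """Stack matrices for encounters that have a prediction time."""
    ids: list[str] = []
    mats: list[np.ndarray] = []
    for enc in encounters:
        if prediction_time(enc) is None:
            continue
        ids.append(enc.patient_id)
        mats.append(build_matrix(enc, stats))
    if not mats:
        return ids, np.zeros((0, N_ROWS, N_STEPS))
    return ids, np.stack(mats)


def save_matrices(path: str, ids: list[str], matrices: np.ndarray) -> None:
    """Persist matrices to HDF5, one dataset per patient id."""
    import h5py

    with h5py.File(path, "w") as f:
        for pid, mat in zip(ids, matrices):
            f.create_dataset(f"patients/{pid}", data=mat)


def load_matrices(path: str) -> tuple[list[str], np.ndarray]:
    import h5py

    ids: list[str] = []
    mats: list[np.ndarray] = []
    with h5py.File(path, "r") as f:
        grp = f["patients"]
        for pid in sorted(grp.keys()):
            ids.append(pid)
            mats.append(np.asarray(grp[pid]))
    return ids, np.stack(mats) if mats else np.zeros((0, N_ROWS, N_STEPS))
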