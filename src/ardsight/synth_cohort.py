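"""Seedable synthetic EHR cohort generator.

Encounters are produced by a simple latent-deterioration model: a
per-patient indicator drawn at the configured prevalence selects patients
whose SpO2 trace ramps down through 97% (the prediction time) and then
92% (respiratory failure), with correlated pre-prediction elevation of
respiratory rate and heart rate scaled by ``deterioration_signal_strength``.
A lagged ARDS ICD code follows respiratory failure by a lognormal delay.
Six auxiliary outcomes are drawn conditionally on the deterioration
indicator, and a configurable fraction of patients carries pre-admission
ICD history inside the 1000-hour look-back window.

Everything is driven by a single ``numpy`` generator seeded from the
config, so identical configs yield identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ardsight.features import TIME_VARYING_FEATURES
from ardsight.labels import Encounter, Event, Observation

__all__ = ["CohortConfig", "generate_cohort", "FEATURE_BASELINES"]

#: (mean, sd) of each time-varying feature for non-deteriorating patients.
FEATURE_BASELINES = {
    "SysBP": (122.0, 16.0),
    "DiasBP": (72.0, 11.0),
    "HR": (85.0, 13.0),
    "Temp": (36.9, 0.5),
    "RespRate": (17.0, 2.5),
    "SpO2": (98.4, 0.55),
    "creatinine": (1.0, 0.4),
    "BUN": (18.0, 7.0),
    "bilirubin": (0.8, 0.4),
    "glucose": (115.0, 30.0),
    "INR": (1.1, 0.2),
    "WBC": (8.5, 2.5),
    "RBC": (4.6, 0.5),
    "platelets": (240.0, 60.0),
    "neutrophil_pct": (62.0, 8.0),
    "lymphocyte_pct": (26.0, 7.0),
    "monocyte_pct": (7.0, 2.0),
    "hematocrit": (40.0, 5.0),
    "lactate": (1.4, 0.6),
    "AST": (28.0, 10.0),
    "ALT": (30.0, 12.0),
}

_VITALS = ("SysBP", "DiasBP", "HR", "Temp", "RespRate", "SpO2")

# Pre-prediction drift per unit signal strength for deteriorating patients,
# in feature units at the prediction time.  Kept well under one baseline SD
# so single encounters are ambiguous and sample size buys real accuracy.
_DRIFT = {"RespRate": 1.6, "HR": 3.5, "lactate": 0.3, "WBC": 0.8}

# Benign history codes (none match an outcome code list).
_BENIGN_HISTORY = ("E11.9", "J44.9", "K21.9", "M54.5", "I10")
_HEART_FAILURE_CODE = "I50.9"

# Representative post-admission codes for the auxiliary ICD outcomes.
_AUX_CODES = {
    "covid19": "U07.1",
    "aki": "N17.9",
    "thrombosis": "I26.99",
    "sepsis": "A41.9",
}


@dataclass
class CohortConfig:
    """Knobs for the generative model; defaults give a learnable cohort."""

    n_patients: int = 1000
    n_hospitals: int = 7
    ards_prevalence: float = 0.02
    deterioration_signal_strength: float = 1.0
    icd_lag_hours: tuple[float, float] = (38.0, 0.45)  # lognormal (median, sigma)
    fail_lag_hours: tuple[float, float] = (21.0, 0.45)  # prediction -> failure
    aux_outcome_probs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            # outcome: (P(outcome | deteriorating), P(outcome | not))
            "ards_icd": (1.0, 0.01),
            "covid19": (0.30, 0.06),
            "aki": (0.35, 0.08),
            "thrombosis": (0.20, 0.05),
            "sepsis": (0.45, 0.10),
            "mech_vent": (0.75, 0.04),
        }
    )
    obs_rate_per_hour: float = 0.35  # vitals; labs measured at 1/8 this rate
    history_fraction: float = 0.4
    heart_failure_history_prob: float = 0.08
    benign_dip_fraction: float = 0.6  # non-deteriorating patients with SpO2<97
    silent_failure_fraction: float = 0.06  # dip below 92 without ARDS code
    hospital_shift_scale: float = 0.25  # per-hospital mean shift, in SDs
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if not 0 < self.ards_prevalence < 1:
            raise ValueError("ards_prevalence must be in (0, 1)")
        if self.deterioration_signal_strength < 0:
            raise ValueError("deterioration_signal_strength must be >= 0")
        if self.icd_lag_hours[0] <= 0:
            raise ValueError("icd_lag_hours median must be > 0")
        for name, (p1, p0) in self.aux_outcome_probs.items():
            if not (0 <= p1 <= 1 and 0 <= p0 <= 1):
                raise ValueError(f"aux_outcome_probs[{name!r}] out of [0,1]")
        for frac in (
            self.history_fraction,
            self.benign_dip_fraction,
            self.silent_failure_fraction,
            self.heart_failure_history_prob,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0,1]")
        if self.obs_rate_per_hour <= 0:
            raise ValueError("obs_rate_per_hour must be > 0")


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _sample_times(rng: np.random.Generator, rate: float, los: float) -> np.ndarray:
    """Poisson-process event times on [0, los], sorted."""
    n = rng.poisson(rate * los)
    return np.sort(rng.uniform(0.0, los, size=n))


def generate_cohort(config: CohortConfig) -> list[Encounter]:
    """Generate the synthetic cohort; deterministic in ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # per-hospital, per-feature site shift (fractions of the feature SD)
    shift = rng.normal(
        0.0, config.hospital_shift_scale, size=(config.n_hospitals, len(TIME_VARYING_FEATURES))
    )
    feat_index = {f: i for i, f in enumerate(TIME_VARYING_FEATURES)}

    encounters: list[Encounter] = []
    base_admission = 0.0  # absolute hours at epoch of first admission
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        hospital = int(rng.integers(config.n_hospitals))
        age = float(np.clip(rng.normal(62.0, 16.0), 18.0, 100.0))
        sex = "male" if rng.random() < 0.5 else "female"
        destined = bool(rng.random() < config.ards_prevalence)
        s = config.deterioration_signal_strength

        if destined:
            t_pred = float(rng.uniform(4.0, 28.0))
            t_fail = t_pred + _lognormal(rng, *config.fail_lag_hours)
            t_icd = t_fail + _lognormal(rng, *config.icd_lag_hours)
            los = t_icd + float(rng.uniform(12.0, 96.0))
            ramp_start = max(0.5, t_pred - float(rng.uniform(6.0, 16.0)))
        else:
            los = float(np.clip(_lognormal(rng, 48.0, 0.8), 4.0, 400.0))
            t_pred = t_fail = t_icd = None
            ramp_start = None
            if rng.random() < config.benign_dip_fraction:
                t_pred = float(rng.uniform(2.0, max(2.5, 0.6 * los)))
                if rng.random() < config.silent_failure_fraction:
                    t_fail = t_pred + float(rng.uniform(1.0, 24.0))
                    t_fail = min(t_fail, los - 0.5)

        obs: list[Observation] = []
        events: list[Event] = []

        def spo2_level(t: float) -> float:
            base = 98.4
            if destined:
                if t < ramp_start:
                    return base
                if t < t_pred:
                    frac = (t - ramp_start) / (t_pred - ramp_start)
                    return base - frac * (base - 96.8)
                if t < t_fail:
                    frac = (t - t_pred) / max(t_fail - t_pred, 1e-9)
                    return 96.8 - frac * (96.8 - 91.3)
                return 90.5
            return base

        def drift(feature: str, t: float) -> float:
            if not destined or feature not in _DRIFT or ramp_start is None:
                return 0.0
            frac = float(np.clip((t - ramp_start) / max(t_pred - ramp_start, 1e-9), 0, 1))
            return s * _DRIFT[feature] * frac

        for feature in TIME_VARYING_FEATURES:
            mean, sd = FEATURE_BASELINES[feature]
            rate = (
                config.obs_rate_per_hour
                if feature in _VITALS
                else config.obs_rate_per_hour / 8.0
            )
            times = _sample_times(rng, rate, los)
            site = shift[hospital, feat_index[feature]] * sd
            for t in times:
                if feature == "SpO2":
                    val = spo2_level(t) + rng.normal(0.0, 0.55)
                    if destined:
                        # keep the planned crossings the first ones: noise may
                        # not breach 97 before t_pred nor 92 before t_fail
                        if t < t_pred:
                            val = max(val, 97.0)
                        elif t < t_fail:
                            val = max(val, 92.0)
                    val = float(np.clip(val, 50.0, 100.0))
                else:
                    val = float(mean + site + drift(feature, t) + rng.normal(0.0, sd))
                obs.append(Observation(feature, round(val, 3), round(float(t), 4)))

        # guaranteed threshold crossings for deteriorating patients; benign
        # dips for the configured fraction of the rest
        if destined:
            obs.append(
                Observation("SpO2", round(float(rng.uniform(95.6, 96.8)), 3), round(t_pred, 4))
            )
            obs.append(
                Observation("SpO2", round(float(rng.uniform(89.5, 91.8)), 3), round(t_fail, 4))
            )
        elif t_pred is not None:
            obs.append(
                Observation("SpO2", round(float(rng.uniform(93.5, 96.8)), 3), round(t_pred, 4))
            )
            if t_fail is not None:
                obs.append(
                    Observation("SpO2", round(float(rng.uniform(89.5, 91.8)), 3), round(t_fail, 4))
                )

        # occasional blood-gas measurements (labeling inputs, not features);
        # non-qualifying (ratio >= 300) so respiratory failure always arrives
        # via the SpO2 trace and never precedes the prediction time
        if rng.random() < 0.12:
            t = float(rng.uniform(0.0, los))
            fio2 = float(rng.uniform(0.21, 0.4))
            pao2 = 300.0 * fio2 + float(rng.uniform(5.0, 60.0))
            gas_time = round(t, 4)
            obs.append(Observation("FiO2", round(fio2, 3), gas_time))
            obs.append(Observation("PaO2", round(pao2, 2), gas_time))

        # pre-admission ICD history
        if rng.random() < config.history_fraction:
            for _ in range(int(rng.integers(1, 4))):
                code = str(rng.choice(_BENIGN_HISTORY))
                t_hist = -float(rng.uniform(1.0, 1000.0))
                events.append(Event("icd", code, round(t_hist, 4)))
        if rng.random() < config.heart_failure_history_prob:
            events.append(
                Event("icd", _HEART_FAILURE_CODE, round(-float(rng.uniform(1.0, 1000.0)), 4))
            )

        # interventions before the prediction time (informative constants)
        p_abx = 0.40 if destined else 0.25
        p_o2 = 0.45 if destined else 0.20
        anchor = t_pred if t_pred is not None else los * 0.5
        if rng.random() < p_abx:
            events.append(Event("antibiotics", "", round(float(rng.uniform(0.0, anchor)), 4)))
        if rng.random() < p_o2:
            events.append(
                Event("supplemental_o2", "", round(float(rng.uniform(0.0, anchor)), 4))
            )

        # auxiliary outcomes, conditionally independent given the indicator
        probs = config.aux_outcome_probs
        p1, p0 = probs.get("mech_vent", (0.0, 0.0))
        if rng.random() < (p1 if destined else p0):
            t_mv = (
                t_fail + float(rng.uniform(0.0, 12.0))
                if destined
                else float(rng.uniform(1.0, los))
            )
            events.append(Event("mech_vent", "", round(min(t_mv, los), 4)))
        for outcome, code in _AUX_CODES.items():
            p1, p0 = probs.get(outcome, (0.0, 0.0))
            if rng.random() < (p1 if destined else p0):
                events.append(Event("icd", code, round(float(rng.uniform(0.5, los)), 4)))

        # ARDS ICD coding: lagged for deteriorating patients; rare code noise
        # for patients who never experience respiratory failure
        p1, p0 = probs.get("ards_icd", (1.0, 0.0))
        if destined:
            if rng.random() < p1:
                events.append(Event("icd", "J80", round(t_icd, 4)))
        elif t_fail is None and rng.random() < p0:
            events.append(Event("icd", "J80", round(float(rng.uniform(0.5, los)), 4)))

        obs.sort(key=lambda o: (o.time, o.feature))
        events.sort(key=lambda e: (e.time, e.event_type, e.code))
        admission_abs = base_admission + i * 24.0
        encounters.append(
            Encounter(
                patient_id=pid,
                admission_time=admission_abs,
                discharge_time=round(los, 4),
                observations=obs,
                events=events,
                hospital_id=f"H{hospital}",
                age=round(age, 2),
                sex=sex,
            )
        )
    return encounters
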