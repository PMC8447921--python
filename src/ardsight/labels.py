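"""Gold-standard outcome labeling from physiologic traces and ICD events.

An encounter is labeled with seven binary outcomes.  The primary outcome
(ARDS with verified respiratory failure) requires both a *new* ARDS ICD
code and a physiologic respiratory-failure criterion, each occurring at or
after the prediction time (the first SpO2 reading below 97%).  A code is
"new" when it appears after admission and is absent from the 1000 hours of
pre-admission history.

All times are float hours relative to admission (admission = 0); event
times may be negative for pre-admission history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Observation",
    "Event",
    "Encounter",
    "OutcomeVector",
    "OUTCOME_NAMES",
    "ICD_CODE_SETS",
    "prediction_time",
    "respiratory_failure_onset",
    "ards_icd_onset",
    "label_outcomes",
    "inclusion_filter",
    "lookahead_intervals",
    "label_cohort",
]

HISTORY_WINDOW_HOURS = 1000.0
SPO2_PREDICTION_THRESHOLD = 97.0
SPO2_FAILURE_THRESHOLD = 92.0
PF_RATIO_THRESHOLD = 300.0
DEFAULT_FIO2 = 0.21
MIN_LOS_HOURS = 3.0

#: Outcome order: primary first, then the six auxiliary outcomes.
OUTCOME_NAMES = (
    "primary_ards_resp_failure",
    "ards_icd",
    "covid19",
    "aki",
    "thrombosis",
    "sepsis",
    "mech_vent_after_drop",
)

# Printed code lists, dots removed; matching is prefix-based so that e.g.
# J96.00 satisfies J96.0.
ICD_CODE_SETS = {
    "ards": ("J80", "J960", "J962", "J969", "51881"),
    "covid19": ("U071", "B9721", "B9729", "J1281", "B342"),
    "aki": ("N17", "N19", "R34"),
    "thrombosis": ("I12", "I26", "I63", "I67", "I74", "I80", "I81", "I82"),
    "sepsis": ("A40", "A41", "R652", "T8112", "T8144", "O85", "O8604"),
}

#: Heart-failure history codes (constant model input, not an outcome).
HEART_FAILURE_CODES = ("I50", "428")


@dataclass(frozen=True)
class Observation:
    feature: str
    value: float
    time: float  # hours from admission


@dataclass(frozen=True)
class Event:
    event_type: str  # icd | antibiotics | supplemental_o2 | mech_vent | ...
    code: str
    time: float  # hours from admission; negative = pre-admission history


@dataclass
class Encounter:
    """One hospital stay with its observation and event streams."""

    patient_id: str
    admission_time: float  # absolute hours; internal times are relative
    discharge_time: float  # hours from admission
    observations: list[Observation] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    hospital_id: str = "H0"
    age: Optional[float] = None
    sex: Optional[str] = None  # "male" | "female"

    def feature_observations(self, feature: str) -> list[Observation]:
        obs = [o for o in self.observations if o.feature == feature]
        obs.sort(key=lambda o: o.time)
        return obs

    @property
    def length_of_stay(self) -> float:
        return self.discharge_time


@dataclass
class OutcomeVector:
    """The 7 gold-standard booleans plus the anchoring timestamps."""

    primary_ards_resp_failure: bool = False
    ards_icd: bool = False
    covid19: bool = False
    aki: bool = False
    thrombosis: bool = False
    sepsis: bool = False
    mech_vent_after_drop: bool = False
    prediction_time: Optional[float] = None
    resp_failure_onset: Optional[float] = None
    ards_icd_onset: Optional[float] = None

    def as_array(self) -> list[int]:
        return [int(getattr(self, name)) for name in OUTCOME_NAMES]


def _normalize_code(code: str) -> str:
    return code.replace(".", "").strip().upper()


def code_matches(code: str, code_set: Sequence[str]) -> bool:
    """Dot-insensitive prefix match against a printed code list."""
    norm = _normalize_code(code)
    return any(norm.startswith(c) for c in code_set)


def prediction_time(enc: Encounter) -> Optional[float]:
    """First time SpO2 falls strictly below 97% at or after admission."""
    for obs in enc.feature_observations("SpO2"):
        if obs.time >= 0 and obs.value < SPO2_PREDICTION_THRESHOLD:
            return obs.time
    return None


def respiratory_failure_onset(enc: Encounter) -> Optional[float]:
    """Earliest SpO2 < 92 or PaO2/FiO2 < 300.

    FiO2 for the ratio is the last-known FiO2 at the PaO2 measurement time
    (0.21 if never recorded).  Raises ``ValueError`` on nonpositive FiO2.
    """
    candidates: list[float] = []
    for obs in enc.feature_observations("SpO2"):
        if obs.time >= 0 and obs.value < SPO2_FAILURE_THRESHOLD:
            candidates.append(obs.time)
            break

    fio2_trace = enc.feature_observations("FiO2")
    for f in fio2_trace:
        if f.value <= 0:
            raise ValueError(
                f"encounter {enc.patient_id}: nonpositive FiO2 {f.value} at {f.time}h"
            )
    for obs in enc.feature_observations("PaO2"):
        if obs.time < 0:
            continue
        fio2 = DEFAULT_FIO2
        for f in fio2_trace:
            if f.time <= obs.time:
                fio2 = f.value
            else:
                break
        if obs.value / fio2 < PF_RATIO_THRESHOLD:
            candidates.append(obs.time)
            break
    return min(candidates) if candidates else None


def _new_code_onset(enc: Encounter, code_set: Sequence[str]) -> Optional[float]:
    """Earliest post-admission time of a code, unless seen in the look-back.

    Implements the novelty rule: any matching code with time in
    [-1000 h, 0) disqualifies the outcome entirely.
    """
    post: list[float] = []
    for ev in enc.events:
        if ev.event_type != "icd" or not code_matches(ev.code, code_set):
            continue
        if -HISTORY_WINDOW_HOURS <= ev.time < 0:
            return None
        if ev.time >= 0:
            post.append(ev.time)
    return min(post) if post else None


def ards_icd_onset(enc: Encounter) -> Optional[float]:
    """Earliest new ARDS ICD code time (1000-hour novelty rule applied)."""
    return _new_code_onset(enc, ICD_CODE_SETS["ards"])


def heart_failure_history(enc: Encounter) -> bool:
    """Any heart-failure code strictly before the prediction-relevant window."""
    return any(
        ev.event_type == "icd" and code_matches(ev.code, HEART_FAILURE_CODES)
        for ev in enc.events
        if ev.time < 0
    )


def label_outcomes(enc: Encounter) -> OutcomeVector:
    """Compute all 7 gold-standard outcomes for one encounter."""
    t_pred = prediction_time(enc)
    t_fail = respiratory_failure_onset(enc)
    t_icd = ards_icd_onset(enc)

    out = OutcomeVector(
        prediction_time=t_pred,
        resp_failure_onset=t_fail,
        ards_icd_onset=t_icd,
    )
    out.ards_icd = t_icd is not None
    out.primary_ards_resp_failure = (
        t_icd is not None
        and t_fail is not None
        and t_pred is not None
        and t_icd >= t_pred
        and t_fail >= t_pred
    )
    for name in ("covid19", "aki", "thrombosis", "sepsis"):
        setattr(out, name, _new_code_onset(enc, ICD_CODE_SETS[name]) is not None)
    out.mech_vent_after_drop = t_pred is not None and any(
        ev.event_type == "mech_vent" and ev.time > t_pred for ev in enc.events
    )
    return out


def inclusion_filter(enc: Encounter) -> bool:
    """LOS >= 3 h and a prediction time exists."""
    los = enc.discharge_time
    return los >= MIN_LOS_HOURS and prediction_time(enc) is not None


def lookahead_intervals(
    labeled: Iterable[tuple[Encounter, OutcomeVector]],
) -> tuple[list[float], list[float]]:
    """Hours from prediction time to ARDS ICD onset and to failure onset.

    Only encounters with both endpoints present contribute; negative
    differences are excluded.
    """
    to_icd: list[float] = []
    to_fail: list[float] = []
    for _, out in labeled:
        if out.prediction_time is None:
            continue
        if out.ards_icd_onset is not None:
            d = out.ards_icd_onset - out.prediction_time
            if d >= 0:
                to_icd.append(d)
        if out.resp_failure_onset is not None:
            d = out.resp_failure_onset - out.prediction_time
            if d >= 0:
                to_fail.append(d)
    return to_icd, to_fail


def label_cohort(
    encounters: Iterable[Encounter],
) -> list[tuple[Encounter, OutcomeVector]]:
    return [(enc, label_outcomes(enc)) for enc in encounters]
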