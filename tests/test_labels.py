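"""Labeler worked examples and brute-force cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ardsight.labels import (
    ICD_CODE_SETS,
    OUTCOME_NAMES,
    Event,
    ards_icd_onset,
    inclusion_filter,
    label_cohort,
    label_outcomes,
    lookahead_intervals,
    prediction_time,
    respiratory_failure_onset,
)
from tests.conftest import make_encounter


class TestPredictionTime:
    def test_first_strict_crossing(self):
        enc = make_encounter(spo2=[(1, 98), (2, 96), (3, 91)])
        assert prediction_time(enc) == 2

    def test_all_normal_is_absent(self):
        enc = make_encounter(spo2=[(1, 98), (5, 97), (9, 99)])
        assert prediction_time(enc) is None

    def test_exact_threshold_does_not_trigger(self):
        # oracle: scan all observations for value strictly below 97
        trace = [(1, 97.0), (4, 95.0)]
        oracle = min((t for t, v in trace if v < 97), default=None)
        enc = make_encounter(spo2=trace)
        assert prediction_time(enc) == oracle == 4

    def test_pre_admission_spo2_ignored(self):
        enc = make_encounter(spo2=[(-5, 90), (2, 96)])
        assert prediction_time(enc) == 2

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 200, allow_nan=False),
                st.floats(60, 100, allow_nan=False),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_scan_oracle(self, trace):
        enc = make_encounter(spo2=trace)
        oracle = min((t for t, v in trace if v < 97.0), default=None)
        assert prediction_time(enc) == oracle


class TestRespiratoryFailureOnset:
    def test_spo2_crossing(self):
        enc = make_encounter(spo2=[(2, 93), (5, 91)])
        assert respiratory_failure_onset(enc) == 5

    def test_pf_ratio_with_last_known_fio2(self):
        # oracle by hand: 80 / 0.30 = 266.7 < 300 at 3h
        assert 80 / 0.30 < 300
        enc = make_encounter(
            spo2=[(1, 95)],
            observations=[("FiO2", 0.30, 2.0), ("PaO2", 80.0, 3.0)],
        )
        assert respiratory_failure_onset(enc) == 3

    def test_default_fio2_room_air(self):
        # 70 / 0.21 = 333 >= 300: no failure on room air
        enc = make_encounter(observations=[("PaO2", 70.0, 3.0)])
        assert respiratory_failure_onset(enc) is None
        # 60 / 0.21 = 285.7 < 300
        enc = make_encounter(observations=[("PaO2", 60.0, 3.0)])
        assert respiratory_failure_onset(enc) == 3

    def test_no_qualifying_observation(self):
        enc = make_encounter(spo2=[(2, 93), (5, 92)])
        assert respiratory_failure_onset(enc) is None

    def test_nonpositive_fio2_is_data_error(self):
        enc = make_encounter(observations=[("FiO2", 0.0, 1.0), ("PaO2", 90.0, 2.0)])
        with pytest.raises(ValueError, match="FiO2"):
            respiratory_failure_onset(enc)


class TestArdsIcdOnset:
    def test_simple_new_code(self):
        enc = make_encounter(events=[("icd", "J80", 59.0)])
        assert ards_icd_onset(enc) == 59

    def test_pre_admission_code_excludes(self):
        enc = make_encounter(
            events=[("icd", "J80", 59.0), ("icd", "J96.0", -200.0)]
        )
        assert ards_icd_onset(enc) is None

    def test_min_over_qualifying_events(self):
        events = [("icd", "J96.2", 30.0), ("icd", "J80", 10.0)]
        oracle = min(t for _, c, t in events)
        enc = make_encounter(events=events)
        assert ards_icd_onset(enc) == oracle == 10

    def test_prefix_matching_dot_insensitive(self):
        assert ards_icd_onset(make_encounter(events=[("icd", "J96.00", 12.0)])) == 12
        assert ards_icd_onset(make_encounter(events=[("icd", "518.81", 12.0)])) == 12
        assert ards_icd_onset(make_encounter(events=[("icd", "J97", 12.0)])) is None

    def test_lookback_window_is_1000_hours(self):
        enc = make_encounter(events=[("icd", "J80", 59.0), ("icd", "J80", -1001.0)])
        assert ards_icd_onset(enc) == 59


class TestLabelOutcomes:
    def test_primary_composition(self):
        enc = make_encounter(
            spo2=[(1, 96), (4, 90)], events=[("icd", "J80", 59.0)]
        )
        out = label_outcomes(enc)
        assert out.primary_ards_resp_failure
        assert out.ards_icd
        assert not any(
            getattr(out, n)
            for n in ("covid19", "aki", "thrombosis", "sepsis", "mech_vent_after_drop")
        )

    def test_failure_without_code_is_not_primary(self):
        enc = make_encounter(spo2=[(1, 96), (4, 90)])
        out = label_outcomes(enc)
        assert not out.primary_ards_resp_failure and not out.ards_icd

    def test_pre_prediction_events_do_not_leak(self):
        # ARDS code before the SpO2 drop: not "subsequent development"
        enc = make_encounter(spo2=[(10, 96), (12, 90)], events=[("icd", "J80", 5.0)])
        assert not label_outcomes(enc).primary_ards_resp_failure

    def test_mech_vent_strictly_after_prediction(self):
        enc = make_encounter(spo2=[(5, 96)], events=[("mech_vent", "", 5.0)])
        assert not label_outcomes(enc).mech_vent_after_drop
        enc = make_encounter(spo2=[(5, 96)], events=[("mech_vent", "", 5.1)])
        assert label_outcomes(enc).mech_vent_after_drop

    def test_seven_outcomes(self):
        out = label_outcomes(make_encounter())
        assert len(out.as_array()) == 7

    def test_agrees_with_brute_force_scan(self, small_cohort):
        """Independent re-scan over the raw streams, no shared helpers."""

        def norm(code):
            return code.replace(".", "").upper()

        def brute(enc):
            t_pred = None
            for o in sorted(enc.observations, key=lambda o: o.time):
                if o.feature == "SpO2" and o.time >= 0 and o.value < 97:
                    t_pred = o.time
                    break
            fails = []
            for o in sorted(enc.observations, key=lambda o: o.time):
                if o.time < 0:
                    continue
                if o.feature == "SpO2" and o.value < 92:
                    fails.append(o.time)
                if o.feature == "PaO2":
                    fio2 = 0.21
                    for f in sorted(enc.observations, key=lambda x: x.time):
                        if f.feature == "FiO2" and f.time <= o.time:
                            fio2 = f.value
                    if o.value / fio2 < 300:
                        fails.append(o.time)
            t_fail = min(fails) if fails else None

            def onset(codes):
                pre = [
                    e for e in enc.events
                    if e.event_type == "icd"
                    and -1000 <= e.time < 0
                    and any(norm(e.code).startswith(c) for c in codes)
                ]
                if pre:
                    return None
                post = [
                    e.time for e in enc.events
                    if e.event_type == "icd"
                    and e.time >= 0
                    and any(norm(e.code).startswith(c) for c in codes)
                ]
                return min(post) if post else None

            t_icd = onset(ICD_CODE_SETS["ards"])
            return {
                "primary_ards_resp_failure": (
                    t_icd is not None and t_fail is not None and t_pred is not None
                    and t_icd >= t_pred and t_fail >= t_pred
                ),
                "ards_icd": t_icd is not None,
                "covid19": onset(ICD_CODE_SETS["covid19"]) is not None,
                "aki": onset(ICD_CODE_SETS["aki"]) is not None,
                "thrombosis": onset(ICD_CODE_SETS["thrombosis"]) is not None,
                "sepsis": onset(ICD_CODE_SETS["sepsis"]) is not None,
                "mech_vent_after_drop": t_pred is not None and any(
                    e.event_type == "mech_vent" and e.time > t_pred for e in enc.events
                ),
            }

        for enc, out in label_cohort(small_cohort):
            expected = brute(enc)
            for name in OUTCOME_NAMES:
                assert getattr(out, name) == expected[name], (enc.patient_id, name)


class TestInclusionFilter:
    def test_short_stay_excluded(self):
        assert not inclusion_filter(make_encounter(spo2=[(1, 96)], discharge=2.9))

    def test_no_drop_excluded(self):
        assert not inclusion_filter(make_encounter(spo2=[(1, 98)], discharge=100))

    def test_boundary_inclusive(self):
        assert inclusion_filter(make_encounter(spo2=[(1, 96)], discharge=3.0))


class TestLookaheadIntervals:
    def test_subtraction(self):
        enc = make_encounter(spo2=[(2, 96), (23, 90)], events=[("icd", "J80", 40.0)])
        to_icd, to_fail = lookahead_intervals(label_cohort([enc]))
        assert to_fail == [21.0]
        assert to_icd == [38.0]

    def test_empty_cohort(self):
        assert lookahead_intervals([]) == ([], [])

    def test_median_echoes_configured_lag(self):
        """Bootstrap the generator's own lag draws as the oracle."""
        from ardsight.synth_cohort import CohortConfig, generate_cohort

        cfg = CohortConfig(n_patients=1200, ards_prevalence=0.25, seed=7)
        cohort = generate_cohort(cfg)
        labeled = label_cohort(cohort)
        to_icd, to_fail = lookahead_intervals(
            [(e, o) for e, o in labeled if o.primary_ards_resp_failure]
        )
        # lognormal(median 21, sigma 0.45) failure lag; icd lag median 38 more
        rng = np.random.default_rng(7)
        draws_fail = 21.0 * np.exp(0.45 * rng.standard_normal((2000, len(to_fail))))
        lo, hi = np.quantile(np.median(draws_fail, axis=1), [0.005, 0.995])
        assert lo <= np.median(to_fail) <= hi
        draws_icd = draws_fail + 38.0 * np.exp(
            0.45 * rng.standard_normal((2000, len(to_icd)))
        )
        lo, hi = np.quantile(np.median(draws_icd, axis=1), [0.005, 0.995])
        assert lo <= np.median(to_icd) <= hi


class TestInvariantProperties:
    def test_prediction_before_failure(self, small_cohort):
        for enc, out in label_cohort(small_cohort):
            if out.prediction_time is not None and out.resp_failure_onset is not None:
                assert out.prediction_time <= out.resp_failure_onset

    def test_idempotence(self, small_cohort):
        first = [o.as_array() for _, o in label_cohort(small_cohort)]
        second = [o.as_array() for _, o in label_cohort(small_cohort)]
        assert first == second

    def test_removing_ards_code_never_creates_primary(self, small_cohort):
        from dataclasses import replace

        from ardsight.labels import code_matches

        for enc in small_cohort:
            stripped = replace(
                enc,
                events=[
                    e for e in enc.events
                    if not (e.event_type == "icd" and code_matches(e.code, ICD_CODE_SETS["ards"]))
                ],
            )
            before = label_outcomes(enc).primary_ards_resp_failure
            after = label_outcomes(stripped).primary_ards_resp_failure
            assert not (after and not before)
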