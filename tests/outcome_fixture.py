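"""Hand-built fixture covering every clause of the hospitalisation definition.

Each scenario fixes a participant record plus events and the hand-computed
expected outcomes.  Scenarios are instantiated once per arm (2 x 25 = 50
records) since endpoint derivation is arm-blind.
"""

import numpy as np
import pandas as pd

from epidex.cohort import EVENT_COLUMNS

_SCENARIOS = []


def scenario(name, *, events=(), expected, admitted=False, first_med=2.0,
             consent=1.0, discharge=8.0, has_db=True, followup_end=504.0):
    _SCENARIOS.append(dict(name=name, events=events, expected=expected,
                           admitted=admitted, first_med=first_med, consent=consent,
                           discharge=discharge, has_db=has_db,
                           followup_end=followup_end))


def E(kind, start, end=np.nan, triage=np.nan, reg=np.nan, cause="bronchiolitis",
      source="medical_record", study_hosp=True, resp="", ae=""):
    return dict(kind=kind, start_h=start, end_h=end, triage_h=triage,
                registration_h=reg, cause=cause, source=source,
                at_study_hospital=study_hosp, respiratory_support=resp, ae_code=ae)


# --- clause 1: inpatient admission ------------------------------------------
scenario("admission_3h", events=[E("inpatient_admission", 3.0, 50.0)],
         expected=dict(primary_hosp_7d=True, hosp_bronch_21d=True,
                       allcause_admission_7d=True, allcause_admission_21d=True))
scenario("admission_at_168h_boundary", events=[E("inpatient_admission", 168.0, 200.0)],
         expected=dict(primary_hosp_7d=True, hosp_bronch_21d=True))
scenario("admission_169h_only", events=[E("inpatient_admission", 169.0, 200.0)],
         expected=dict(primary_hosp_7d=False, hosp_bronch_21d=True,
                       allcause_admission_7d=False, allcause_admission_21d=True))
scenario("other_cause_admission_5h", events=[E("inpatient_admission", 5.0, 40.0, cause="other")],
         expected=dict(primary_hosp_7d=False, hosp_bronch_21d=False,
                       allcause_admission_7d=True, allcause_admission_21d=True))
scenario("admitted_at_enrolment", admitted=True, discharge=3.0,
         events=[E("inpatient_admission", 1.0, 80.0)],
         expected=dict(primary_hosp_7d=True, hosp_at_enrolment=True,
                       admission_los_h=79.0, enrolment_ed_los_h=np.nan))

# --- clause 2: enrolment ED / observation stay >= 12 h ----------------------
scenario("enrol_los_exactly_12h", first_med=2.0, discharge=14.0,
         expected=dict(primary_hosp_7d=True, hosp_at_enrolment=True,
                       enrolment_ed_los_h=12.0))
scenario("enrol_los_11.9h", first_med=2.0, discharge=13.9,
         expected=dict(primary_hosp_7d=False, hosp_at_enrolment=False,
                       enrolment_ed_los_h=11.9))
scenario("no_med_consent_clock_13h", first_med=np.nan, consent=1.0, discharge=14.0,
         expected=dict(primary_hosp_7d=True, hosp_at_enrolment=True,
                       enrolment_ed_los_h=13.0))
scenario("no_med_consent_clock_11.5h", first_med=np.nan, consent=1.0, discharge=12.5,
         expected=dict(primary_hosp_7d=False, enrolment_ed_los_h=11.5))

# --- clause 3: return ED stays, min(triage, registration) clock -------------
scenario("return_stay_12.7h", events=[E("ed_return", 100.3, 113.0, triage=100.5, reg=100.3)],
         expected=dict(primary_hosp_7d=True, allcause_ed_visits_21d=1))
scenario("return_stay_11.9h", events=[E("ed_return", 50.0, 61.9, triage=50.0, reg=50.0)],
         expected=dict(primary_hosp_7d=False, allcause_ed_visits_21d=1))
scenario("return_tied_clocks", events=[E("ed_return", 60.0, 73.0, triage=60.0, reg=60.0)],
         expected=dict(primary_hosp_7d=True))
scenario("return_other_cause_13h", events=[E("ed_return", 60.0, 73.0, triage=60.0, reg=60.0,
                                             cause="other")],
         expected=dict(primary_hosp_7d=False, allcause_admission_7d=True))
scenario("combined_contiguous_13h",
         events=[E("ed_return", 100.0, 107.0, triage=100.0, reg=100.0),
                 E("ed_return", 107.5, 113.0, triage=107.5, reg=107.5)],
         expected=dict(primary_hosp_7d=True, allcause_ed_visits_21d=1))
scenario("split_stays_gap_2h",
         events=[E("ed_return", 100.0, 107.0, triage=100.0, reg=100.0),
                 E("ed_return", 109.0, 114.5, triage=109.0, reg=109.0)],
         expected=dict(primary_hosp_7d=False, allcause_ed_visits_21d=2))
scenario("return_spans_168h_boundary",
         events=[E("ed_return", 167.0, 180.0, triage=167.0, reg=167.0)],
         expected=dict(primary_hosp_7d=True, hosp_bronch_21d=True))

# --- confirmation rules ------------------------------------------------------
scenario("survey_study_hosp_unmatched",
         events=[E("inpatient_admission", 30.0, 60.0, source="caregiver_survey")],
         expected=dict(primary_hosp_7d=False, allcause_admission_21d=False))
scenario("survey_study_hosp_matched",
         events=[E("inpatient_admission", 30.0, 60.0, source="caregiver_survey"),
                 E("inpatient_admission", 31.0, 60.0)],
         expected=dict(primary_hosp_7d=True, allcause_admission_7d=True))
scenario("survey_nonstudy_no_db", has_db=False,
         events=[E("inpatient_admission", 30.0, 60.0, source="caregiver_survey",
                   study_hosp=False)],
         expected=dict(primary_hosp_7d=True))
scenario("survey_nonstudy_db_unmatched", has_db=True,
         events=[E("inpatient_admission", 30.0, 60.0, source="caregiver_survey",
                   study_hosp=False)],
         expected=dict(primary_hosp_7d=False))
scenario("survey_nonstudy_db_matched", has_db=True,
         events=[E("inpatient_admission", 30.0, 60.0, source="caregiver_survey",
                   study_hosp=False),
                 E("inpatient_admission", 30.5, 60.0, source="admin_db", study_hosp=False)],
         expected=dict(primary_hosp_7d=True, allcause_admission_7d=True))

# --- ICU rule and counts -----------------------------------------------------
scenario("icu_cpap", events=[E("inpatient_admission", 2.0, 90.0),
                             E("icu_admission", 10.0, 60.0, resp="cpap")],
         expected=dict(primary_hosp_7d=True, icu_21d=True))
scenario("icu_no_support", events=[E("inpatient_admission", 2.0, 90.0),
                                   E("icu_admission", 10.0, 60.0, resp="none")],
         expected=dict(primary_hosp_7d=True, icu_21d=False))
scenario("zero_events", expected=dict(
    primary_hosp_7d=False, hosp_at_enrolment=False, hosp_bronch_21d=False,
    allcause_admission_21d=False, allcause_admission_7d=False, icu_21d=False,
    provider_visits_21d=0, allcause_ed_visits_21d=0))
scenario("death_100h_truncates", followup_end=504.0,
         events=[E("provider_visit", 100.0, cause="other", ae="death")],
         expected=dict(missing_primary_hosp_7d=True, missing_allcause_admission_21d=True))

assert len(_SCENARIOS) == 25


def build_fixture():
    """Returns (participants, events, expected) with 50 records (25 x 2 arms)."""
    p_rows, e_rows, exp_rows = [], [], []
    i = 0
    for arm in ("placebo", "epidex"):
        for sc in _SCENARIOS:
            i += 1
            pid = f"F{i:03d}"
            p_rows.append({
                "participant_id": pid, "site_id": "S01",
                "site_has_admin_db": sc["has_db"], "arm": arm,
                "consent_time_h": sc["consent"], "first_med_time_h": sc["first_med"],
                "ed_discharge_time_h": sc["discharge"],
                "admitted_at_enrolment": sc["admitted"],
                "followup_end_h": sc["followup_end"],
                "survey_day7_symptoms_resolved": 1.0,
                "survey_day21_symptoms_resolved": 1.0,
                "out_of_pocket_expenses": 50.0,
            })
            for e in sc["events"]:
                e_rows.append({"participant_id": pid, **e,
                               "ae_organ_class": "", "ae_severity": ""})
            exp_rows.append({"participant_id": pid, "scenario": sc["name"],
                             **sc["expected"]})
    participants = pd.DataFrame(p_rows)
    events = pd.DataFrame(e_rows, columns=EVENT_COLUMNS) if e_rows else pd.DataFrame(
        columns=EVENT_COLUMNS)
    return participants, events, pd.DataFrame(exp_rows)
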