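"""Endpoint derivation from participant records and healthcare-contact events.

The study definition of hospitalisation is any of:

  1. admission to an inpatient ward,
  2. an ED length of stay of 12 h or greater (boundary inclusive),
  3. a combined ED and observation-unit length of stay of 12 h or greater.

The enrolment-visit ED length of stay runs from the first study-medication
time (or consent, when no study medication was received) to discharge from
the ED or observation unit.  Return-visit stays run from the earlier of
triage and registration.  Caregiver-reported admissions and ED visits at
study hospitals only count once confirmed on medical-record review; at sites
with administrative-database access the same applies to non-study-hospital
reports, while at sites without such access the caregiver's report is used
as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PRIMARY_WINDOW_H = 168.0     # 7 days
FOLLOWUP_WINDOW_H = 504.0    # 21 days
LOS_THRESHOLD_H = 12.0
CONTIGUITY_GAP_H = 1.0       # ED/observation intervals <= 1 h apart are one stay
MATCH_WINDOW_H = 24.0        # survey report matches a record event within 24 h

ADMISSION_KINDS = ("inpatient_admission", "icu_admission")


@dataclass(frozen=True)
class OutcomeWindow:
    primary_window_h: float = PRIMARY_WINDOW_H
    followup_window_d: float = 21.0
    los_threshold_h: float = LOS_THRESHOLD_H

    def __post_init__(self):
        if min(self.primary_window_h, self.followup_window_d, self.los_threshold_h) <= 0:
            raise ValueError("outcome windows must be strictly positive")

    @property
    def followup_window_h(self) -> float:
        return self.followup_window_d * 24.0


class DataError(ValueError):
    pass


def follow_clock_zero(record) -> float:
    """Hours since ED arrival at which the follow-up clock starts."""
    fm = record["first_med_time_h"]
    return float(fm) if pd.notna(fm) else float(record["consent_time_h"])


def enrolment_ed_los(record) -> float:
    """Enrolment-visit ED (incl. observation unit) length of stay in hours."""
    if pd.isna(record["ed_discharge_time_h"]):
        raise DataError(f"participant {record['participant_id']}: no ED discharge time")
    los = float(record["ed_discharge_time_h"]) - follow_clock_zero(record)
    if los < 0:
        raise DataError(
            f"participant {record['participant_id']}: ED discharge precedes the "
            "length-of-stay clock start"
        )
    return los


def return_visit_los(event) -> float:
    """Return-ED-visit length of stay: end minus min(triage, registration)."""
    t, r = event["triage_h"], event["registration_h"]
    if pd.isna(t) and pd.isna(r):
        raise DataError("return ED visit carries neither triage nor registration time")
    start = np.nanmin([t, r])
    return float(event["end_h"]) - float(start)


def resolve_confirmation(events: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Set per-event ``confirmed`` and ``duplicate`` flags.

    ``confirmed`` marks events that count toward outcomes; ``duplicate`` marks
    caregiver reports matched to a medical-record (or administrative-database)
    event, which are confirmations of that event rather than extra contacts.
    """
    ev = events.copy()
    db = participants.set_index("participant_id")["site_has_admin_db"]
    ev["_has_db"] = ev["participant_id"].map(db).fillna(False).astype(bool)
    confirmed = np.ones(len(ev), dtype=bool)
    duplicate = np.zeros(len(ev), dtype=bool)

    is_survey = (ev["source"] == "caregiver_survey").to_numpy()
    needs_review = ev["kind"].isin(ADMISSION_KINDS + ("ed_return",)).to_numpy()
    record_like = ev[ev["source"].isin(["medical_record", "admin_db"])]
    by_participant = {pid: g for pid, g in record_like.groupby("participant_id")}

    for i in np.flatnonzero(is_survey & needs_review):
        row = ev.iloc[i]
        candidates = by_participant.get(row["participant_id"])

        def matched(sources) -> bool:
            if candidates is None:
                return False
            g = candidates[candidates["source"].isin(sources) & (candidates["kind"] == row["kind"])]
            return bool((np.abs(g["start_h"] - row["start_h"]) <= MATCH_WINDOW_H).any())

        if row["at_study_hospital"]:
            # study-hospital reports must be confirmed on medical-record review
            if matched(["medical_record"]):
                duplicate[i] = True
            else:
                confirmed[i] = False
        elif row["_has_db"]:
            if matched(["admin_db", "medical_record"]):
                duplicate[i] = True
            else:
                confirmed[i] = False
        # site without database access: the caregiver's report is used as-is

    ev["confirmed"] = confirmed
    ev["duplicate"] = duplicate
    ev["counts"] = confirmed & ~duplicate
    return ev.drop(columns="_has_db")


def _merge_ed_stays(ed_events: pd.DataFrame, gap_h: float = CONTIGUITY_GAP_H) -> list[dict]:
    """Merge contiguous return-ED/observation intervals (gap <= ``gap_h``)."""
    stays = []
    for _, e in ed_events.sort_values("start_h").iterrows():
        start = float(np.nanmin([e["triage_h"], e["registration_h"]])) if (
            pd.notna(e["triage_h"]) or pd.notna(e["registration_h"])
        ) else float(e["start_h"])
        end = float(e["end_h"]) if pd.notna(e["end_h"]) else start
        cause = e["cause"]
        if stays and start - stays[-1]["end"] <= gap_h:
            stays[-1]["end"] = max(stays[-1]["end"], end)
            stays[-1]["causes"].add(cause)
        else:
            stays.append({"start": start, "end": end, "causes": {cause}})
    return stays


def classify_hospitalisation(
    record,
    events: pd.DataFrame,
    window_h: float,
    cause_filter: str = "bronchiolitis",
    los_threshold_h: float = LOS_THRESHOLD_H,
) -> bool:
    """Apply the three-part hospitalisation definition within ``window_h``.

    ``events`` must already carry confirmation flags.  A stay qualifies if it
    starts within the window, even when the 12-h threshold is only crossed
    beyond it (logged as a boundary convention by the pipeline).  The
    enrolment-visit ED/observation stay is by definition bronchiolitis-
    related and counts under either cause filter; return-visit stays count
    toward bronchiolitis outcomes only when attributed to bronchiolitis.
    """
    if cause_filter not in ("bronchiolitis", "all"):
        raise ValueError("cause_filter must be 'bronchiolitis' or 'all'")
    ev = events[events["counts"]] if "counts" in events.columns else events

    # 1. inpatient (or ICU) admission within the window, matching the cause.
    # Admission at the enrolment visit is bronchiolitis-related by definition.
    if bool(record["admitted_at_enrolment"]):
        return True
    adm = ev[ev["kind"].isin(ADMISSION_KINDS) & (ev["start_h"] <= window_h)]
    if cause_filter == "bronchiolitis":
        adm = adm[adm["cause"] == "bronchiolitis"]
    if len(adm):
        return True

    # 2. enrolment ED/observation stay of 12 h or more
    if pd.notna(record["ed_discharge_time_h"]) and not record["admitted_at_enrolment"]:
        if enrolment_ed_los(record) >= los_threshold_h:
            return True

    # 3. return ED stays (contiguous intervals merged) of 12 h or more
    for stay in _merge_ed_stays(ev[ev["kind"] == "ed_return"]):
        if stay["start"] <= window_h and (stay["end"] - stay["start"]) >= los_threshold_h:
            if cause_filter == "all" or "bronchiolitis" in stay["causes"]:
                return True
    return False


def _death_time(events: pd.DataFrame) -> float:
    d = events[events["ae_code"] == "death"]
    return float(d["start_h"].min()) if len(d) else np.inf


OUTCOME_COLUMNS = [
    "participant_id", "primary_hosp_7d", "hosp_at_enrolment", "allcause_admission_21d",
    "provider_visits_21d", "hosp_bronch_21d", "icu_21d", "allcause_admission_7d",
    "allcause_ed_visits_21d", "enrolment_ed_los_h", "admission_los_h",
    "symptoms_resolved_day7", "symptoms_resolved_day21", "out_of_pocket_expenses",
]


def _merge_intervals(starts, ends, causes, gap_h=CONTIGUITY_GAP_H):
    """Merge contiguous (start, end, is_bronch) triples; inputs pre-sorted."""
    stays = []
    for s, e, c in zip(starts, ends, causes):
        if stays and s - stays[-1][1] <= gap_h:
            prev = stays[-1]
            stays[-1] = (prev[0], max(prev[1], e), prev[2] or c)
        else:
            stays.append((s, e, c))
    return stays


def derive_outcomes(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    window: OutcomeWindow | None = None,
) -> pd.DataFrame:
    """Derive the full outcome set for every participant.

    Returns one row per participant with outcome values and, for each outcome
    ``x``, a boolean ``missing_x`` column.  Binary outcomes that could not be
    observed through their window (death or loss to follow-up before the
    window closed, without a prior qualifying event) are flagged missing
    rather than set false; counts over incompletely observed windows are
    likewise flagged.  Missing outcomes are never imputed.
    """
    window = window or OutcomeWindow()
    if "counts" not in events.columns:
        events = resolve_confirmation(events, participants)
    w7, w21, thr = window.primary_window_h, window.followup_window_h, window.los_threshold_h

    # flatten events into numpy, sliced per participant for speed
    ev = events[events["counts"]].copy()
    pid_order = participants["participant_id"].to_numpy()
    pid_pos = {p: i for i, p in enumerate(pid_order)}
    ev["_pos"] = ev["participant_id"].map(pid_pos)
    ev = ev[ev["_pos"].notna()].sort_values(["_pos", "start_h"])
    e_pos = ev["_pos"].to_numpy(int)
    e_kind = ev["kind"].to_numpy(object)
    e_start = ev["start_h"].to_numpy(float)
    e_end = ev["end_h"].to_numpy(float)
    e_triage = ev["triage_h"].to_numpy(float)
    e_reg = ev["registration_h"].to_numpy(float)
    e_bronch = (ev["cause"] == "bronchiolitis").to_numpy()
    e_resp_ok = ev["respiratory_support"].isin(["cpap", "intubation"]).to_numpy()
    e_death = (ev["ae_code"] == "death").to_numpy()
    bounds = np.searchsorted(e_pos, np.arange(len(participants) + 1))

    admitted_v = participants["admitted_at_enrolment"].fillna(False).to_numpy(bool)
    discharge_v = pd.to_numeric(participants["ed_discharge_time_h"], errors="coerce").to_numpy(float)
    firstmed_v = pd.to_numeric(participants["first_med_time_h"], errors="coerce").to_numpy(float)
    consent_v = pd.to_numeric(participants["consent_time_h"], errors="coerce").to_numpy(float)
    clock0_v = np.where(np.isfinite(firstmed_v), firstmed_v, consent_v)
    fend_v = (pd.to_numeric(participants["followup_end_h"], errors="coerce").to_numpy(float)
              if "followup_end_h" in participants.columns else np.full(len(participants), w21))
    fend_v = np.where(np.isfinite(fend_v), fend_v, w21)

    def col(name):
        if name in participants.columns:
            return pd.to_numeric(participants[name], errors="coerce").to_numpy(float)
        return np.full(len(participants), np.nan)

    res7_v, res21_v, exp_v = (col("survey_day7_symptoms_resolved"),
                              col("survey_day21_symptoms_resolved"),
                              col("out_of_pocket_expenses"))

    rows = []
    for i in range(len(participants)):
        lo_i, hi_i = bounds[i], bounds[i + 1]
        sl = slice(lo_i, hi_i)
        kinds = e_kind[sl]
        starts = e_start[sl]
        ends = e_end[sl]
        bronch = e_bronch[sl]
        is_adm = (kinds == "inpatient_admission") | (kinds == "icu_admission")
        is_ed = kinds == "ed_return"
        death_h = float(starts[e_death[sl]].min()) if e_death[sl].any() else np.inf
        observed_to = min(fend_v[i], death_h)
        admitted = bool(admitted_v[i])

        enrol_los = discharge_v[i] - clock0_v[i] if np.isfinite(discharge_v[i]) else np.nan
        if np.isfinite(enrol_los) and enrol_los < 0:
            raise DataError(
                f"participant {pid_order[i]}: ED discharge precedes the "
                "length-of-stay clock start")
        long_enrol = (not admitted) and np.isfinite(enrol_los) and enrol_los >= thr

        # merged return-ED stays (clock = min(triage, registration))
        if is_ed.any():
            t_, r_ = e_triage[sl][is_ed], e_reg[sl][is_ed]
            s_ = np.where(np.isfinite(t_) | np.isfinite(r_),
                          np.fmin(t_, r_), starts[is_ed])
            en_ = np.where(np.isfinite(ends[is_ed]), ends[is_ed], s_)
            order = np.argsort(s_)
            ed_stays = _merge_intervals(s_[order], en_[order], bronch[is_ed][order])
        else:
            ed_stays = []

        def classify(window_h, bronch_only):
            if admitted:
                return True
            sel = is_adm & (starts <= window_h)
            if bronch_only:
                sel &= bronch
            if sel.any():
                return True
            if long_enrol:
                return True
            for s_, e_, c_ in ed_stays:
                if s_ <= window_h and (e_ - s_) >= thr and (c_ or not bronch_only):
                    return True
            return False

        def flag(value, window_h):
            return value, (not value) and (observed_to < window_h)

        primary, m_primary = flag(classify(w7, True), w7)
        hosp_enrol = admitted or long_enrol
        bronch21, m_bronch21 = flag(classify(w21, True), w21)
        all21, m_all21 = flag(classify(w21, False), w21)
        all7, m_all7 = flag(classify(w7, False), w7)

        icu_sel = (kinds == "icu_admission") & (starts <= w21) & bronch & e_resp_ok[sl]
        icu21, m_icu21 = flag(bool(icu_sel.any()), w21)

        n_provider = int((kinds == "provider_visit").sum())
        n_ed = sum(1 for s_, _, _ in ed_stays if s_ <= w21)
        counts_missing = observed_to < w21

        # disposition: exactly one of the two enrolment length-of-stay fields
        if admitted:
            if is_adm.any():
                j = int(np.flatnonzero(is_adm)[0])
                admission_los = (ends[j] - starts[j]) if np.isfinite(ends[j]) else np.nan
            else:
                admission_los = np.nan
            enrol_los_out = np.nan
        else:
            admission_los = np.nan
            enrol_los_out = enrol_los

        res7, res21, expenses = res7_v[i], res21_v[i], exp_v[i]

        rows.append({
            "participant_id": pid_order[i],
            "primary_hosp_7d": primary, "missing_primary_hosp_7d": m_primary,
            "hosp_at_enrolment": hosp_enrol, "missing_hosp_at_enrolment": False,
            "allcause_admission_21d": all21, "missing_allcause_admission_21d": m_all21,
            "provider_visits_21d": n_provider + n_ed,
            "missing_provider_visits_21d": counts_missing,
            "hosp_bronch_21d": bronch21, "missing_hosp_bronch_21d": m_bronch21,
            "icu_21d": icu21, "missing_icu_21d": m_icu21,
            "allcause_admission_7d": all7, "missing_allcause_admission_7d": m_all7,
            "allcause_ed_visits_21d": n_ed, "missing_allcause_ed_visits_21d": counts_missing,
            "enrolment_ed_los_h": enrol_los_out,
            "missing_enrolment_ed_los_h": (not admitted) and pd.isna(enrol_los_out),
            "admission_los_h": admission_los,
            "missing_admission_los_h": admitted and pd.isna(admission_los),
            "symptoms_resolved_day7": res7, "missing_symptoms_resolved_day7": pd.isna(res7),
            "symptoms_resolved_day21": res21, "missing_symptoms_resolved_day21": pd.isna(res21),
            "out_of_pocket_expenses": expenses,
            "missing_out_of_pocket_expenses": pd.isna(expenses),
        })
    return pd.DataFrame(rows)


def check_outcome_nesting(outcomes: pd.DataFrame) -> None:
    """Assert the logical nesting of the hospitalisation outcomes.

    enrolment admission => primary => 21-day bronchiolitis admission =>
    21-day all-cause admission; 7-day all-cause => 21-day all-cause.
    Missing-flagged values are exempt (their false values are placeholders).
    """
    o = outcomes

    def ok(a, b, miss_b):
        viol = o[a].astype(bool) & ~o[b].astype(bool) & ~o[miss_b].astype(bool)
        if viol.any():
            bad = o.loc[viol, "participant_id"].tolist()[:5]
            raise AssertionError(f"nesting violated: {a} without {b} for {bad}")

    ok("hosp_at_enrolment", "primary_hosp_7d", "missing_primary_hosp_7d")
    ok("primary_hosp_7d", "hosp_bronch_21d", "missing_hosp_bronch_21d")
    ok("hosp_bronch_21d", "allcause_admission_21d", "missing_allcause_admission_21d")
    ok("allcause_admission_7d", "allcause_admission_21d", "missing_allcause_admission_21d")
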