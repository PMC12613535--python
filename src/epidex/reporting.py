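"""Analysis populations, baseline tables, participant-flow counts, and
protocol-deviation / safety summaries.

Populations:
  * intention-to-treat (ITT): randomised participants with an available
    primary outcome who did not withdraw consent;
  * per-protocol: additionally eligible, received both epinephrine treatments
    with correct timing, and the dexamethasone dose within +/-5% of target;
  * restricted per-protocol: additionally took the second dexamethasone dose,
    unless admitted to hospital within the 40-h second-dose window.

Baseline tables carry no inferential statistics: categoricals as n (%),
continuous variables as mean (SD) when roughly symmetric (|sample skewness|
<= 1) and median (IQR) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DOSE_TOLERANCE
from .outcomes import ADMISSION_KINDS

POPULATIONS = ("itt", "per_protocol", "per_protocol_restricted")
SECOND_DOSE_WINDOW_H = 40.0       # anchored at the first dexamethasone dose
TIMING_TOLERANCE_MIN = 15.0       # second epinephrine 30 +/- 15 min after the first
SKEWNESS_CUTOFF = 1.0

SAFETY_OUTCOMES = ("gi_bleeding", "serious_bacterial_infection", "severe_varicella", "death")


class CountError(ValueError):
    pass


def _dose_ok(participants: pd.DataFrame) -> pd.Series:
    target = participants["dex_target_mg"].astype(float)
    given = participants["dex_given_mg"].astype(float)
    rel = (given - target).abs() / target.replace(0, np.nan)
    return (rel <= DOSE_TOLERANCE + 1e-9).fillna(False)


def _admitted_within_window(participants: pd.DataFrame, events: pd.DataFrame,
                            window_h: float = SECOND_DOSE_WINDOW_H) -> pd.Series:
    adm = events[events["kind"].isin(ADMISSION_KINDS) & (events["start_h"] <= window_h)]
    hit = set(adm["participant_id"])
    return participants["participant_id"].isin(hit) | participants["admitted_at_enrolment"].astype(bool)


def population_filter(
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    population: str,
    events: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select an analysis population; returns (subset, exclusion log)."""
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    df = participants.merge(
        outcomes[["participant_id", "missing_primary_hosp_7d"]], on="participant_id")
    reasons = pd.Series("", index=df.index, dtype=object)

    def exclude(mask, reason):
        new = mask & (reasons == "")
        reasons[new] = reason

    exclude(df["withdrawal"].fillna(False).astype(bool), "consent withdrawn")
    exclude(df["missing_primary_hosp_7d"].astype(bool), "primary outcome unavailable")
    if population in ("per_protocol", "per_protocol_restricted"):
        exclude(~df["eligible"].astype(bool), "ineligible")
        exclude(df["epi_doses_given"].astype(float) < 2, "incomplete ED medications")
        exclude(~df["epi_timing_ok"].fillna(False).astype(bool), "incorrect medication timing")
        exclude(~_dose_ok(df), "dose outside +/-5% tolerance")
    if population == "per_protocol_restricted":
        missed_second = ~df["second_dex_taken"].fillna(False).astype(bool)
        if events is not None:
            rescued = _admitted_within_window(df, events)
        else:
            rescued = df["admitted_at_enrolment"].astype(bool)
        exclude(missed_second & ~rescued, "second oral dose missed")
    keep = reasons == ""
    log = df.loc[~keep, ["participant_id", "arm"]].copy()
    log["reason"] = reasons[~keep]
    return participants[participants["participant_id"].isin(df.loc[keep, "participant_id"])], log


# --------------------------------------------------------------------------- #
# baseline table
# --------------------------------------------------------------------------- #

DEFAULT_BASELINE_VARS = [
    "age_days", "sex", "weight_kg", "race", "indigenous_status", "prematurity",
    "eczema", "family_atopy", "household_smoke", "prenatal_smoke", "breastfeeding",
    "previous_wheeze", "daycare", "virus_type", "symptom_onset_hours_before_enrolment",
    "rdai", "oxygen_saturation", "respiratory_rate", "heart_rate", "temperature_c",
]


def baseline_table(participants: pd.DataFrame,
                   variables: list[str] | None = None) -> pd.DataFrame:
    """Per-arm baseline summary table; purely descriptive.

    The normality rule is applied per continuous variable: mean (SD) when
    |sample skewness| <= 1, else median (IQR); the rule used is recorded in
    the ``summary_type`` column.
    """
    variables = variables or [v for v in DEFAULT_BASELINE_VARS if v in participants.columns]
    rows = []
    for var in variables:
        s_all = participants[var]
        is_cat = s_all.dtype == object or s_all.dtype == bool or s_all.nunique(dropna=True) <= 2
        if is_cat:
            for level in sorted(s_all.dropna().unique(), key=str):
                row = {"variable": var, "level": str(level), "summary_type": "n_percent"}
                for arm, g in participants.groupby("arm"):
                    n = int((g[var] == level).sum())
                    denom = int(g[var].notna().sum())
                    row[f"{arm}"] = f"{n} ({100 * n / denom:.1f}%)" if denom else "0"
                rows.append(row)
        else:
            x = pd.to_numeric(s_all, errors="coerce")
            skew = stats.skew(x.dropna()) if x.notna().sum() > 2 else 0.0
            use_mean = abs(skew) <= SKEWNESS_CUTOFF
            row = {"variable": var, "level": "",
                   "summary_type": "mean_sd" if use_mean else "median_iqr",
                   "skewness": round(float(skew), 3)}
            for arm, g in participants.groupby("arm"):
                v = pd.to_numeric(g[var], errors="coerce").dropna()
                if use_mean:
                    row[f"{arm}"] = f"{v.mean():.2f} ({v.std(ddof=1):.2f})"
                else:
                    q1, q3 = v.quantile([0.25, 0.75])
                    row[f"{arm}"] = f"{v.median():.2f} ({q1:.2f}-{q3:.2f})"
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# participant flow
# --------------------------------------------------------------------------- #

@dataclass
class ConsortCounts:
    screened: int
    eligible: int
    excluded: int
    excluded_by_reason: dict[str, int]
    randomised: int
    randomised_by_arm: dict[str, int]
    received_intervention: dict[str, int]
    lost_to_followup: dict[str, int]
    discontinued: dict[str, int]
    analysed: dict[str, int]
    withdrawals_by_reason: dict[str, dict[str, int]]
    screened_age_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def consort_counts(screening: pd.DataFrame, participants: pd.DataFrame,
                   outcomes: pd.DataFrame) -> ConsortCounts:
    """Participant-flow counts with internal consistency checks."""
    if screening[["age_days", "sex"]].isna().any().any():
        raise CountError("screening log must record age and sex for every screened patient")
    screened = len(screening)
    eligible = int(screening["eligible"].sum())
    excl = screening[~screening["eligible"].astype(bool)]
    excluded_by_reason = excl["exclusion_reason"].value_counts().to_dict()
    if sum(excluded_by_reason.values()) != screened - eligible:
        raise CountError("exclusion reasons do not sum to screened - eligible")
    randomised = len(participants)
    by_arm = participants.groupby("arm").size().to_dict()
    received = participants[participants["epi_doses_given"].astype(float) > 0] \
        .groupby("arm").size().to_dict()
    lost = participants[participants["lost_to_followup"].astype(bool)] \
        .groupby("arm").size().to_dict()
    disc = participants[participants["withdrawal"].astype(bool)].groupby("arm").size().to_dict()
    itt, _ = population_filter(participants, outcomes, "itt")
    analysed = itt.groupby("arm").size().to_dict()
    wd = participants[participants["withdrawal"].astype(bool)]
    withdrawals = {
        arm: g["withdrawal_reason"].value_counts().to_dict() for arm, g in wd.groupby("arm")
    }
    for arm, n in analysed.items():
        if n > by_arm.get(arm, 0):
            raise CountError(f"analysed exceeds randomised in arm {arm}")
    age = screening["age_days"].astype(float)
    return ConsortCounts(
        screened=screened, eligible=eligible, excluded=screened - eligible,
        excluded_by_reason=excluded_by_reason, randomised=randomised,
        randomised_by_arm={k: int(v) for k, v in by_arm.items()},
        received_intervention={k: int(v) for k, v in received.items()},
        lost_to_followup={k: int(v) for k, v in lost.items()},
        discontinued={k: int(v) for k, v in disc.items()},
        analysed={k: int(v) for k, v in analysed.items()},
        withdrawals_by_reason=withdrawals,
        screened_age_summary={"mean": float(age.mean()), "sd": float(age.std(ddof=1))},
    )


# --------------------------------------------------------------------------- #
# deviations and safety
# --------------------------------------------------------------------------- #

def deviation_and_safety_summary(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    outcomes: pd.DataFrame,
    deviation_log: pd.DataFrame | None = None,
) -> dict:
    """Deviation percentages on ITT denominators and the safety-event table.

    Safety events are counted at most once per participant per outcome; the
    adverse-event code table groups by the opaque organ-class string.
    """
    itt, _ = population_filter(participants, outcomes, "itt")
    itt_ids = set(itt["participant_id"])
    denom = itt.groupby("arm").size().to_dict()

    if deviation_log is None:
        dose_bad = ~_dose_ok(participants)
        dev = participants[
            dose_bad | (participants["epi_doses_given"].astype(float) < 2)
            | ~participants["epi_timing_ok"].fillna(False).astype(bool)
            | ~participants["second_dex_taken"].fillna(False).astype(bool)
        ][["participant_id", "arm"]]
    else:
        dev = deviation_log.merge(participants[["participant_id", "arm"]], on="participant_id")
    dev = dev[dev["participant_id"].isin(itt_ids)].drop_duplicates("participant_id")
    dev_counts = dev.groupby("arm").size().to_dict()
    deviation_pct = {
        arm: 100.0 * dev_counts.get(arm, 0) / n for arm, n in denom.items()
    }

    ae = events[events["ae_code"].astype(str) != ""].merge(
        participants[["participant_id", "arm"]], on="participant_id")
    safety_rows = []
    for code in SAFETY_OUTCOMES:
        sub = ae[ae["ae_code"] == code].drop_duplicates("participant_id")
        for arm, n in denom.items():
            cnt = int((sub["arm"] == arm).sum())
            safety_rows.append({"outcome": code, "arm": arm, "participants_with_event": cnt,
                                "percent": 100.0 * cnt / n})
    organ = (ae.drop_duplicates(["participant_id", "ae_code"])
             .groupby(["ae_organ_class", "ae_severity", "arm"]).size()
             .reset_index(name="n_participants"))
    return {
        "itt_denominators": {k: int(v) for k, v in denom.items()},
        "deviation_percent_by_arm": deviation_pct,
        "safety_table": pd.DataFrame(safety_rows),
        "organ_class_table": organ,
    }
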