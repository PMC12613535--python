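"""Synthetic trial-cohort generator.

Produces participant-level records, a long-format healthcare-contact (event)
table, and a latent truth table for an emergency-department bronchiolitis
superiority trial: 1:1 site-stratified permuted-block allocation, a log-link
(relative-risk scale) outcome model with site random intercepts, enrolment-
visit clocks supporting the length-of-stay definitions, follow-up contacts
over 21 days, surveys, loss to follow-up, missingness and protocol
deviations.

Clock conventions (decimal hours):
  * enrolment-visit clocks (``consent_time_h``, ``first_med_time_h``,
    ``ed_discharge_time_h``) are measured from ED arrival;
  * follow-up event clocks (``start_h`` etc. in the events table) are
    measured from the first study-medication time, or from consent when no
    study medication was received — the same zero the length-of-stay
    definition uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from .config import CohortConfig, PROB_CLAMP

ARMS = ("placebo", "epidex")
EVENT_COLUMNS = [
    "participant_id", "kind", "start_h", "end_h", "triage_h", "registration_h",
    "cause", "source", "at_study_hospital", "respiratory_support",
    "ae_code", "ae_organ_class", "ae_severity",
]

# Generator means used to centre covariates so the configured baseline log
# risk stays the marginal control-arm risk (up to log-scale convexity).
_COVARIATE_MEANS = {
    "age_days": 212.5,
    "prematurity": 0.10,
    "eczema": 0.15,
    "family_atopy": 0.30,
    "household_smoke": 0.20,
    "prenatal_smoke": 0.10,
    "breastfeeding": 0.60,
    "previous_wheeze": 0.25,
    "daycare": 0.25,
    "virus_rsv": 0.55,
    "rdai": 17 * 0.35,
    "symptom_onset_hours_before_enrolment": 48.0,
}

SAFETY_CODES = {
    "gi_bleeding": ("gastrointestinal", "moderate"),
    "serious_bacterial_infection": ("infection", "severe"),
    "severe_varicella": ("infection", "severe"),
    "death": ("fatal", "fatal"),
}

FOLLOWUP_END_H = 21 * 24.0


class AllocationError(ValueError):
    pass


def assign_permuted_blocks(site_sequence, block_size: int, seed: int) -> np.ndarray:
    """Site-stratified permuted-block 1:1 allocation.

    Within each site, arms are assigned in randomly permuted blocks of
    ``block_size`` (half per arm), in enrolment order.  Deterministic in
    ``seed``.
    """
    if block_size % 2 != 0 or block_size < 2:
        raise AllocationError(
            "block_size must be even and >= 2: blocks allocate the two arms "
            "in a 1:1 ratio, half the block per arm"
        )
    sites = np.asarray(site_sequence)
    if sites.size == 0:
        raise AllocationError("site_sequence must be non-empty")
    rng = child_rng(seed, "allocation")
    arms = np.empty(sites.size, dtype=object)
    half = block_size // 2
    # Deterministic per-site sub-streams: iterate sites in sorted order.
    for site in sorted(pd.unique(sites).tolist()):
        idx = np.flatnonzero(sites == site)
        n_blocks = -(-idx.size // block_size)
        seq = []
        for _ in range(n_blocks):
            block = np.array([0] * half + [1] * half)
            rng.shuffle(block)
            seq.append(block)
        codes = np.concatenate(seq)[: idx.size]
        arms[idx] = np.array(ARMS, dtype=object)[codes]
    return arms


@dataclass
class CohortData:
    """One simulated trial: participants, events, latent truth, screening log."""

    participants: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    screening: pd.DataFrame
    config: CohortConfig
    log: list[str] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("participants", self.participants),
            ("events", self.events),
            ("truth", self.truth),
            ("screening", self.screening),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        cfg = out / "config.yaml"
        cfg.write_text(yaml.safe_dump(self.config.model_dump(mode="json"), sort_keys=True))
        paths["config"] = cfg
        logp = out / "run.log"
        logp.write_text("\n".join(self.log) + ("\n" if self.log else ""))
        paths["log"] = logp
        return paths


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate one complete-data trial cohort under ``config``.

    The latent truth table records each participant's true hospitalisation
    probability, site intercept and realised outcome; the event table is
    constructed so that deriving the primary outcome from it reproduces the
    truth exactly (checked by the outcome-derivation test-suite).
    """
    n = config.n_participants
    log: list[str] = []

    # --- sites and allocation -------------------------------------------------
    rng_sites = child_rng(config.seed, "sites")
    site_idx = rng_sites.choice(config.n_sites, size=n, p=config.resolved_site_weights())
    site_ids = np.array([f"S{i + 1:02d}" for i in range(config.n_sites)], dtype=object)
    n_south = int(round(config.southern_fraction * config.n_sites))
    hemisphere = np.array(
        ["southern" if i >= config.n_sites - n_south else "northern" for i in range(config.n_sites)],
        dtype=object,
    )
    n_db = int(round(config.admin_db_fraction * config.n_sites))
    has_db = np.array([i < n_db for i in range(config.n_sites)])
    arm = assign_permuted_blocks(site_idx, config.block_size, config.seed)

    # --- baseline covariates --------------------------------------------------
    rc = child_rng(config.seed, "covariates")
    age_days = rc.integers(60, 366, size=n)
    sex = np.where(rc.random(n) < 0.5, "female", "male").astype(object)
    weight = np.where(
        sex == "female", rc.normal(7.3, 0.9, n), rc.normal(7.9, 0.95, n)
    )
    weight = np.clip(weight, 3.0, None).round(2)
    race = rc.choice(
        np.array(["white", "black", "asian", "other"], dtype=object),
        size=n, p=[0.55, 0.15, 0.15, 0.15],
    )
    indigenous = rc.choice(
        np.array(["non_indigenous", "first_nations", "metis", "inuit", "maori_pacific"], dtype=object),
        size=n, p=[0.85, 0.05, 0.02, 0.01, 0.07],
    )
    bern = lambda p: (rc.random(n) < p).astype(int)  # noqa: E731
    cov = {
        "prematurity": bern(0.10),
        "eczema": bern(0.15),
        "family_atopy": bern(0.30),
        "household_smoke": bern(0.20),
        "prenatal_smoke": bern(0.10),
        "breastfeeding": bern(0.60),
        "previous_wheeze": bern(0.25),
        "daycare": bern(0.25),
    }
    virus = rc.choice(
        np.array(["rsv", "rhinovirus", "other", "untested"], dtype=object),
        size=n, p=[0.55, 0.15, 0.10, 0.20],
    )
    symptom_onset = rc.gamma(2.0, 24.0, n).round(1)  # hours before enrolment, mean 48
    rdai = rc.binomial(17, 0.35, n)
    o2 = np.clip(rc.normal(96.0, 2.0, n), 85, 100).round(1)
    resp_rate = np.clip(rc.normal(48, 8, n), 25, 90).round(0)
    heart_rate = np.clip(rc.normal(150, 15, n), 100, 220).round(0)
    temp = np.clip(rc.normal(37.4, 0.6, n), 35.5, 41.0).round(1)
    delivery_mdi = bern(0.5)
    eligible = 1 - bern(config.ineligible_rate)

    # --- latent outcome model (log link, relative-risk scale) -----------------
    ro = child_rng(config.seed, "outcome")
    site_u = ro.normal(0.0, config.site_sd, config.n_sites) if config.site_sd > 0 else np.zeros(config.n_sites)
    frame = {
        "age_days": age_days, "rdai": rdai,
        "symptom_onset_hours_before_enrolment": symptom_onset,
        "virus_rsv": (virus == "rsv").astype(int), **cov,
    }
    lp_cov = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        if name not in frame:
            raise KeyError(f"unknown covariate in covariate_effects: {name!r}")
        lp_cov += eff * (frame[name].astype(float) - _COVARIATE_MEANS[name])
    is_active = (arm == "epidex").astype(float)
    log_rr_i = config.log_rr_treatment + config.log_rr_risk_slope * lp_cov
    log_p = config.baseline_log_risk + site_u[site_idx] + lp_cov + is_active * log_rr_i
    p_raw = np.exp(log_p)
    clamped = (p_raw <= PROB_CLAMP) | (p_raw >= 1 - PROB_CLAMP)
    p_true = np.clip(p_raw, PROB_CLAMP, 1 - PROB_CLAMP)
    n_clamped = int(clamped.sum())
    if n_clamped:
        msg = f"clamped {n_clamped}/{n} event probabilities to ({PROB_CLAMP}, {1 - PROB_CLAMP})"
        log.append("WARNING: " + msg if n_clamped > 0.01 * n else msg)
        if n_clamped > 0.01 * n:
            warnings.warn(msg, stacklevel=2)
    hospitalised = ro.random(n) < p_true

    # --- enrolment-visit clocks and dosing ------------------------------------
    re_ = child_rng(config.seed, "events")
    consent = (0.5 + 2.5 * re_.random(n)).round(2)
    no_med = re_.random(n) < config.deviation_rates.get("missed_ed_medication", 0.0) * 0.5
    first_med = np.where(no_med, np.nan, (consent + 0.1 + 0.9 * re_.random(n)).round(2))
    clock0 = np.where(no_med, consent, first_med)  # hours since ED arrival
    dex_target = np.minimum(0.6 * weight, 10.0).round(2)
    dex_given = np.where(no_med, 0.0, dex_target)
    epi_doses = np.where(no_med, 0, 2)
    epi_timing_ok = ~no_med
    second_dex_taken = ~no_med
    second_dex_time = np.where(
        second_dex_taken, (np.nan_to_num(first_med) + 24 + 6 * re_.random(n)).round(2), np.nan
    )

    # disposition: how the realised outcome manifests at the enrolment visit
    mode = np.full(n, "discharged", dtype=object)
    u = re_.random(n)
    mode[hospitalised & (u < 0.65)] = "admit_enrol"
    mode[hospitalised & (u >= 0.65) & (u < 0.85)] = "long_ed"
    mode[hospitalised & (u >= 0.85)] = "return_admission"
    admitted_at_enrolment = mode == "admit_enrol"

    ed_los = np.where(
        mode == "long_ed", 12.0 + 8.0 * re_.random(n), 1.5 + 8.4 * re_.random(n)
    )  # long stays >= 12 h, others < 10 h
    admit_start = (1.0 + 5.0 * re_.random(n)).round(2)  # ward transfer, h after clock zero
    ed_discharge = np.where(admitted_at_enrolment, clock0 + admit_start, clock0 + ed_los).round(2)

    pid = np.array([f"P{i + 1:05d}" for i in range(n)], dtype=object)

    # --- follow-up events -----------------------------------------------------
    ev: list[dict] = []

    def add(i, kind, start, end=np.nan, triage=np.nan, reg=np.nan, cause="bronchiolitis",
            source="medical_record", study_hosp=True, resp="", ae=""):
        ev.append({
            "participant_id": pid[i], "kind": kind, "start_h": round(float(start), 2),
            "end_h": round(float(end), 2) if np.isfinite(end) else np.nan,
            "triage_h": round(float(triage), 2) if np.isfinite(triage) else np.nan,
            "registration_h": round(float(reg), 2) if np.isfinite(reg) else np.nan,
            "cause": cause, "source": source, "at_study_hospital": bool(study_hosp),
            "respiratory_support": resp,
            "ae_code": ae,
            "ae_organ_class": SAFETY_CODES[ae][0] if ae else "",
            "ae_severity": SAFETY_CODES[ae][1] if ae else "",
        })

    # qualifying admissions for truth-positive participants
    for i in np.flatnonzero(mode == "admit_enrol"):
        start = admit_start[i]
        end = start + 24 + 72 * re_.random()
        add(i, "inpatient_admission", start, end)
        if re_.random() < 0.30:  # caregiver also reports it; confirmed duplicate
            add(i, "inpatient_admission", start + re_.random(), end, source="caregiver_survey")
    for i in np.flatnonzero(mode == "return_admission"):
        start = 12 + 148 * re_.random()
        add(i, "inpatient_admission", start, start + 24 + 60 * re_.random())
    # ICU among admitted participants
    for i in np.flatnonzero(hospitalised & (mode != "long_ed")):
        if re_.random() < 0.08:
            start = admit_start[i] + 2 + 22 * re_.random()
            resp = re_.choice(["cpap", "intubation", "none"], p=[0.6, 0.3, 0.1])
            add(i, "icu_admission", start, start + 24 + 48 * re_.random(), resp=resp)

    # background, never-qualifying contacts
    n_provider = re_.poisson(0.7, n)
    for i in range(n):
        for _ in range(n_provider[i]):
            add(i, "provider_visit", 24 + 470 * re_.random(),
                cause="bronchiolitis" if re_.random() < 0.8 else "other",
                source="medical_record" if re_.random() < 0.6 else "caregiver_survey",
                study_hosp=bool(re_.random() < 0.5))
    for i in np.flatnonzero(re_.random(n) < 0.15):  # short return ED visits (< 12 h)
        triage = 24 + 466 * re_.random()
        reg = triage + (re_.random() - 0.5) * 0.4
        lo = min(triage, reg)
        add(i, "ed_return", lo, lo + 1 + 9 * re_.random(), triage=triage, reg=reg,
            cause="bronchiolitis" if re_.random() < 0.7 else "other",
            source="medical_record" if re_.random() < 0.8 else "caregiver_survey",
            study_hosp=bool(re_.random() < 0.8))
    for i in np.flatnonzero(re_.random(n) < 0.04):  # admissions after the 7-day window
        start = 168.5 + 310 * re_.random()
        add(i, "inpatient_admission", start, start + 24 + 48 * re_.random(),
            cause="bronchiolitis" if re_.random() < 0.5 else "other")
    for i in np.flatnonzero(re_.random(n) < 0.02):  # early other-cause admissions
        start = 6 + 154 * re_.random()
        add(i, "inpatient_admission", start, start + 24 + 48 * re_.random(), cause="other")
    # survey-only reports at study hospitals: excluded on record review
    for i in np.flatnonzero(re_.random(n) < 0.03):
        start = 10 + 150 * re_.random()
        add(i, "inpatient_admission", start, start + 24, source="caregiver_survey")

    # safety events
    rs = child_rng(config.seed, "safety")
    for code in SAFETY_CODES:
        rate = config.safety_event_rate * (0.2 if code == "death" else 1.0)
        for i in np.flatnonzero(rs.random(n) < rate):
            add(i, "provider_visit", 12 + 480 * rs.random(), cause="other", ae=code)
            if rs.random() < 0.3 and code != "death":  # repeat event, same participant
                add(i, "provider_visit", 12 + 480 * rs.random(), cause="other", ae=code)

    events = pd.DataFrame(ev, columns=EVENT_COLUMNS)

    # --- follow-up completeness and surveys -----------------------------------
    rf = child_rng(config.seed, "followup")
    lost = rf.random(n) < config.loss_to_followup
    followup_end = np.where(lost, 24 + 480 * rf.random(n), FOLLOWUP_END_H).round(1)
    withdrawal = rf.random(n) < config.withdrawal_rate
    withdrawal_reason = np.where(
        withdrawal,
        rf.choice(np.array(["caregiver_request", "investigator_decision", "adverse_event"],
                           dtype=object), size=n),
        "",
    )
    rsv_ = child_rng(config.seed, "surveys")
    day7_done = (~lost | (followup_end >= 7 * 24)) & (rsv_.random(n) < 0.95)
    day21_done = ~lost & (rsv_.random(n) < 0.92)
    resolved7 = np.where(
        day7_done, (rsv_.random(n) < np.where(hospitalised, 0.30, 0.60)).astype(float), np.nan
    )
    resolved21 = np.where(day21_done, (rsv_.random(n) < 0.90).astype(float), np.nan)
    expenses = np.where(
        day21_done,
        (rsv_.gamma(2.0, 40.0, n) + np.where(hospitalised, rsv_.gamma(2.0, 60.0, n), 0.0)).round(2),
        np.nan,
    )

    # drop events not observed before follow-up ended
    events = events.merge(
        pd.DataFrame({"participant_id": pid, "_fend": followup_end}), on="participant_id"
    )
    events = events[events["start_h"] <= events["_fend"]].drop(columns="_fend").reset_index(drop=True)

    participants = pd.DataFrame({
        "participant_id": pid,
        "site_id": site_ids[site_idx],
        "site_hemisphere": hemisphere[site_idx],
        "site_has_admin_db": has_db[site_idx],
        "arm": arm,
        "eligible": eligible.astype(bool),
        "age_days": age_days,
        "sex": sex,
        "weight_kg": weight,
        "race": race,
        "indigenous_status": indigenous,
        **{k: v.astype(bool) for k, v in cov.items()},
        "virus_type": virus,
        "symptom_onset_hours_before_enrolment": symptom_onset,
        "rdai": rdai,
        "oxygen_saturation": o2,
        "respiratory_rate": resp_rate,
        "heart_rate": heart_rate,
        "temperature_c": temp,
        "delivery_mdi": delivery_mdi.astype(bool),
        "first_episode": ~cov["previous_wheeze"].astype(bool),
        "consent_time_h": consent,
        "first_med_time_h": first_med,
        "ed_discharge_time_h": ed_discharge,
        "admitted_at_enrolment": admitted_at_enrolment,
        "dex_target_mg": dex_target,
        "dex_given_mg": dex_given,
        "epi_doses_given": epi_doses,
        "epi_timing_ok": epi_timing_ok,
        "second_dex_taken": second_dex_taken,
        "second_dex_time_h": second_dex_time,
        "withdrawal": withdrawal,
        "withdrawal_reason": withdrawal_reason,
        "lost_to_followup": lost,
        "followup_end_h": followup_end,
        "survey_day7_completed": day7_done,
        "survey_day7_symptoms_resolved": resolved7,
        "survey_day21_completed": day21_done,
        "survey_day21_symptoms_resolved": resolved21,
        "out_of_pocket_expenses": expenses,
    })

    truth = pd.DataFrame({
        "participant_id": pid,
        "site_id": site_ids[site_idx],
        "arm": arm,
        "p_true": p_true,
        "site_intercept": site_u[site_idx],
        "log_rr_individual": np.where(is_active > 0, log_rr_i, config.log_rr_treatment
                                      + config.log_rr_risk_slope * lp_cov),
        "lp_covariates": lp_cov,
        "hospitalised": hospitalised,
    })

    # --- screening log --------------------------------------------------------
    rscr = child_rng(config.seed, "screening")
    f = config.screening_failure_rate
    n_excluded = int(round(n * f / (1 - f)))
    n_screened = n + n_excluded
    reasons = rscr.choice(
        np.array(["age_out_of_range", "prior_enrolment", "severe_comorbidity", "no_consent"],
                 dtype=object),
        size=n_excluded, p=[0.35, 0.1, 0.25, 0.3],
    )
    screening = pd.DataFrame({
        "screening_id": [f"SC{i + 1:05d}" for i in range(n_screened)],
        "age_days": np.concatenate([age_days, rscr.integers(20, 420, n_excluded)]),
        "sex": np.concatenate([sex, np.where(rscr.random(n_excluded) < 0.5, "female", "male")]),
        "eligible": np.concatenate([np.ones(n, bool), np.zeros(n_excluded, bool)]),
        "exclusion_reason": np.concatenate([np.full(n, "", dtype=object), reasons]),
        "participant_id": np.concatenate([pid, np.full(n_excluded, "", dtype=object)]),
    })

    log.append(f"generated cohort: n={n}, sites={config.n_sites}, seed={config.seed}")
    log.append(f"events generated: {len(events)}")
    return CohortData(participants, events, truth, screening, config, log)


def apply_missingness(
    participants: pd.DataFrame,
    missingness_rates: dict[str, float],
    seed: int,
    dependence: dict[str, tuple[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace values with missing markers at the configured per-variable rates.

    Completely-at-random by default; ``dependence[var] = (driver, log_odds)``
    makes var's missingness depend on the (standardised) driver covariate
    through a logistic model with the same marginal rate.
    """
    dependence = dependence or {}
    out = participants.copy()
    rng = child_rng(seed, "missingness")
    rows = []
    for var, rate in missingness_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"missingness rate for {var!r} must lie in [0, 1]")
        if var not in out.columns:
            raise KeyError(f"unknown variable in missingness_rates: {var!r}")
        n = len(out)
        if var in dependence and dependence[var][1] != 0.0:
            driver, beta = dependence[var]
            z = pd.to_numeric(out[driver], errors="coerce").astype(float)
            z = (z - z.mean()) / (z.std() or 1.0)
            # calibrate the intercept so the marginal rate matches `rate`
            from scipy.optimize import brentq
            from scipy.special import expit
            zv = z.fillna(0.0).to_numpy()
            if rate in (0.0, 1.0):
                p = np.full(n, rate)
            else:
                a = brentq(lambda a_: expit(a_ + beta * zv).mean() - rate, -30, 30)
                p = expit(a + beta * zv)
            mechanism = f"covariate_dependent({driver})"
        else:
            p = np.full(n, rate)
            mechanism = "mcar"
        mask = rng.random(n) < p
        if out[var].dtype == bool:
            out[var] = out[var].astype(object)
        out.loc[mask, var] = np.nan
        rows.append({"variable": var, "mechanism": mechanism,
                     "configured_rate": rate, "realised_rate": mask.mean(),
                     "n_missing": int(mask.sum())})
    return out, pd.DataFrame(rows, columns=["variable", "mechanism", "configured_rate",
                                            "realised_rate", "n_missing"])


DEVIATION_KINDS = ("missed_ed_medication", "dose_out_of_tolerance",
                   "incorrect_timing", "missed_second_dex")
DOSE_TOLERANCE = 0.05  # protocol allows +/- 5% on dose


def apply_protocol_deviations(
    participants: pd.DataFrame, deviation_rates: dict[str, float], seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Perturb dose/adherence fields to create protocol deviations.

    Kinds: missed ED medication (epinephrine doses incomplete), dose outside
    the +/-5% tolerance, incorrect timing of the second epinephrine dose, and
    missed second dexamethasone dose.  Participants who received no study
    medication at all (generated natively so the length-of-stay clock stays
    consistent) are also listed as missed-medication deviants.
    """
    out = participants.copy()
    rng = child_rng(seed, "deviations")
    n = len(out)
    rows = []

    def note(mask, kind):
        for pid_ in out.loc[mask, "participant_id"]:
            rows.append({"participant_id": pid_, "kind": kind})

    for kind, rate in deviation_rates.items():
        if kind not in DEVIATION_KINDS:
            raise KeyError(f"unknown deviation kind: {kind!r}")
        if not 0 <= rate <= 1:
            raise ValueError(f"deviation rate for {kind!r} must lie in [0, 1]")
        mask = rng.random(n) < rate
        if kind == "missed_ed_medication":
            mask &= out["epi_doses_given"].to_numpy() > 0
            out.loc[mask, "epi_doses_given"] = rng.integers(0, 2, int(mask.sum()))
        elif kind == "dose_out_of_tolerance":
            sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
            frac = DOSE_TOLERANCE + 0.01 + 0.15 * rng.random(n)  # just outside +/-5%
            newdose = out["dex_target_mg"] * (1 + sign * frac)
            mask &= out["dex_given_mg"].to_numpy() > 0
            out.loc[mask, "dex_given_mg"] = newdose[mask].round(2)
        elif kind == "incorrect_timing":
            mask &= out["epi_doses_given"].to_numpy() == 2
            out.loc[mask, "epi_timing_ok"] = False
        elif kind == "missed_second_dex":
            mask &= out["second_dex_taken"].to_numpy()
            out.loc[mask, "second_dex_taken"] = False
            out.loc[mask, "second_dex_time_h"] = np.nan
        note(mask, kind)
    native = (out["epi_doses_given"].to_numpy() == 0) & out["first_med_time_h"].isna().to_numpy()
    note(native, "missed_ed_medication")
    dev_log = pd.DataFrame(rows, columns=["participant_id", "kind"]).drop_duplicates()
    return out, dev_log.reset_index(drop=True)
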