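"""Configuration models for simulation, priors, sampling and design.

All models are pydantic so YAML configs are validated before any stage runs.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

# Design constants of the trial: control-arm hospitalisation probability 0.35,
# target absolute reduction 0.08, 5% loss to follow-up.
CONTROL_RISK = 0.35
TARGET_DIFFERENCE = 0.08
ACTIVE_RISK = CONTROL_RISK - TARGET_DIFFERENCE
LOSS_TO_FOLLOWUP = 0.05

PROB_CLAMP = 1e-6  # generated event probabilities clamped to [1e-6, 1 - 1e-6]


class CohortConfig(BaseModel):
    """Parameters of the synthetic-cohort generator.

    Defaults reproduce the design assumptions of the trial: 1:1 site-stratified
    permuted-block allocation across 12 sites, control-arm hospitalisation risk
    0.35, an absolute risk reduction of 0.08 under the active combination
    (relative risk 0.27/0.35), modest site-level heterogeneity and a 5% loss to
    follow-up.
    """

    n_participants: int = Field(864, gt=0)
    n_sites: int = Field(12, gt=0)
    site_weights: Optional[list[float]] = None  # uniform when None
    southern_fraction: float = Field(0.25, ge=0, le=1)  # fraction of sites in the southern hemisphere
    admin_db_fraction: float = Field(0.5, ge=0, le=1)  # sites with administrative-database access
    block_size: int = Field(4, ge=2)
    baseline_log_risk: float = math.log(CONTROL_RISK)
    log_rr_treatment: float = math.log(ACTIVE_RISK / CONTROL_RISK)
    site_sd: float = Field(0.15, ge=0)
    covariate_effects: dict[str, float] = Field(
        default_factory=lambda: {
            "age_days": -0.0015,
            "prematurity": 0.35,
            "previous_wheeze": 0.30,
            "eczema": 0.10,
            "family_atopy": 0.10,
            "household_smoke": 0.20,
            "prenatal_smoke": 0.15,
            "breastfeeding": -0.15,
            "virus_rsv": 0.15,
            "rdai": 0.04,
        }
    )
    # Optional risk-dependent treatment effect: per-participant log RR is
    # log_rr_treatment + log_rr_risk_slope * (centred covariate linear predictor).
    log_rr_risk_slope: float = 0.0
    missingness_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "survey_day7_symptoms_resolved": 0.05,
            "survey_day21_symptoms_resolved": 0.08,
            "out_of_pocket_expenses": 0.08,
            "breastfeeding": 0.02,
            "prenatal_smoke": 0.03,
        }
    )
    # Covariate-dependent missingness: variable -> (driver covariate, log-odds per unit).
    missingness_dependence: dict[str, tuple[str, float]] = Field(default_factory=dict)
    deviation_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "missed_ed_medication": 0.02,
            "dose_out_of_tolerance": 0.03,
            "incorrect_timing": 0.03,
            "missed_second_dex": 0.08,
        }
    )
    loss_to_followup: float = Field(LOSS_TO_FOLLOWUP, ge=0, le=1)
    withdrawal_rate: float = Field(0.01, ge=0, le=1)
    ineligible_rate: float = Field(0.01, ge=0, le=1)
    screening_failure_rate: float = Field(0.3, ge=0, lt=1)
    safety_event_rate: float = Field(0.005, ge=0, le=1)
    seed: int = 0

    @field_validator("block_size")
    @classmethod
    def _even_block(cls, v: int) -> int:
        if v % 2 != 0:
            raise ValueError(
                "block_size must be even: permuted blocks allocate arms 1:1, "
                "so each block holds block_size/2 participants per arm"
            )
        return v

    @model_validator(mode="after")
    def _weights(self) -> "CohortConfig":
        if self.site_weights is not None:
            w = np.asarray(self.site_weights, dtype=float)
            if len(w) != self.n_sites:
                raise ValueError("site_weights length must equal n_sites")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("site_weights must sum to 1")
            if (w < 0).any():
                raise ValueError("site_weights must be non-negative")
        for name, rates in (
            ("missingness_rates", self.missingness_rates),
            ("deviation_rates", self.deviation_rates),
        ):
            for k, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"{name}[{k}] must lie in [0, 1]")
        return self

    def resolved_site_weights(self) -> np.ndarray:
        if self.site_weights is None:
            return np.full(self.n_sites, 1.0 / self.n_sites)
        return np.asarray(self.site_weights, dtype=float)


class PriorSpec(BaseModel):
    """Prior for the treatment-effect analyses.

    ``kind``:
      * ``flat`` — uniform on the per-arm risks (two-arm model) or improper
        uniform on regression coefficients (hierarchical structures).
      * ``beta`` — independent Beta priors on the per-arm hospitalisation
        probabilities (two-arm model only).
      * ``normal_logrr`` — normal prior on the log relative risk.
      * ``point`` — degenerate prior at fixed per-arm risks; only meaningful
        for prior-predictive data generation in design calculations.

    The shipped "elicited-like" default (see :func:`elicited_like_prior`) is a
    stand-in with Beta means 0.35 / 0.27 and user-chosen effective sample
    sizes; it is NOT the study's expert-elicited prior, which is published
    separately and not reproduced here.
    """

    kind: Literal["flat", "beta", "normal_logrr", "point"] = "flat"
    # beta: per-arm (a, b) shape pairs; arm 0 = placebo, arm 1 = active.
    beta_placebo: tuple[float, float] = (1.0, 1.0)
    beta_active: tuple[float, float] = (1.0, 1.0)
    # normal_logrr
    logrr_mean: float = 0.0
    logrr_sd: float = Field(10.0, gt=0)
    # point
    point_placebo: float = Field(CONTROL_RISK, gt=0, lt=1)
    point_active: float = Field(ACTIVE_RISK, gt=0, lt=1)
    # nuisance-parameter priors, weakly informative by default
    baseline_mean: float = 0.0  # normal prior mean for the log baseline risk
    coefficient_sd: float = Field(10.0, gt=0)
    site_sd_scale: float = Field(1.0, gt=0)  # half-normal scale for the site SD

    @model_validator(mode="after")
    def _positive_shapes(self) -> "PriorSpec":
        for pair in (self.beta_placebo, self.beta_active):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("beta shape parameters must be strictly positive")
        return self

    @property
    def proper(self) -> bool:
        return self.kind in ("beta", "point", "normal_logrr")


def elicited_like_prior(ess_placebo: float = 40.0, ess_active: float = 40.0) -> PriorSpec:
    """Stand-in informative prior: independent Betas with means 0.35 and 0.27.

    The study's own treatment-effect prior came from a separate expert
    elicitation that is not reproduced here; this synthetic stand-in only has
    the same means, with effective sample sizes set by the caller.
    """
    return PriorSpec(
        kind="beta",
        beta_placebo=(CONTROL_RISK * ess_placebo, (1 - CONTROL_RISK) * ess_placebo),
        beta_active=(ACTIVE_RISK * ess_active, (1 - ACTIVE_RISK) * ess_active),
    )


class McmcSettings(BaseModel):
    """Sampler settings. Reported analyses use >= 1000 draws per chain."""

    n_chains: int = Field(4, ge=1)
    n_warmup: int = Field(1000, ge=10)
    n_draws: int = Field(1000, ge=1)
    seed: int = 0
    target_acceptance: float = Field(0.44, gt=0, lt=1)

    def reduced(self, n_chains: int = 1, n_warmup: int = 400, n_draws: int = 800) -> "McmcSettings":
        """A cheaper copy for simulation loops (design / calibration studies)."""
        return self.model_copy(update={"n_chains": n_chains, "n_warmup": n_warmup, "n_draws": n_draws})


class DesignParams(BaseModel):
    """Average-length-criterion sample-size parameters.

    Study values: criterion 0.09 on the risk-difference scale, 1500
    prior-predictive studies, 5000 posterior draws per study, decision
    threshold 0.99, null risk 0.35, target difference 0.08, 5% attrition.
    """

    criterion_length: float = Field(0.09, gt=0, lt=1)
    n_grid: list[int] = Field(default_factory=lambda: [200, 300, 410, 600, 800, 1000])
    n_outer: int = Field(1500, ge=1)
    posterior_draws: int = Field(5000, ge=100)
    threshold: float = Field(0.99, ge=0, le=1)
    null_risk: float = Field(CONTROL_RISK, gt=0, lt=1)
    target_difference: float = Field(TARGET_DIFFERENCE, gt=0, lt=1)
    loss_to_followup: float = Field(LOSS_TO_FOLLOWUP, ge=0, lt=1)
    prior: PriorSpec = Field(default_factory=lambda: PriorSpec(kind="point"))
    seed: int = 0

    @field_validator("n_grid")
    @classmethod
    def _increasing(cls, v: list[int]) -> list[int]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("n_grid must be strictly increasing")
        return v
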