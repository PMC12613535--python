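"""Pre-specified subgroup interaction analyses and risk-stratified
heterogeneity-of-treatment-effect (HTE) analysis.

Six subgroups are analysed with a relative-risk model carrying main effects
for treatment and subgroup plus their interaction; a positive (negative)
subgroup effect is declared only when the interaction coefficient is above
(below) zero with posterior probability exceeding 99%.

The HTE analysis fits a multivariable hospitalisation-risk model that
ignores treatment assignment, splits participants into ten strata at the
deciles of predicted risk, and reports the posterior median relative risk
with a 95% HDI within each stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .config import McmcSettings, PriorSpec
from .inference import PosteriorDraws, fit_rr_model, hdi, prob_superiority

AGE_CUTOFF_DAYS = 183          # six months
ONSET_CUTOFF_H = 48.0          # boundary inclusive

SUBGROUP_IDS = ("age_lt6m", "onset_48h", "eczema", "family_atopy",
                "hemisphere", "delivery_mode")

RISK_MODEL_COVARIATES = (
    "age_days", "sex", "prematurity", "symptom_onset_hours_before_enrolment",
    "previous_wheeze", "eczema", "family_atopy", "household_smoke",
    "prenatal_smoke", "breastfeeding", "virus_type",
)


def classify_subgroups(participants: pd.DataFrame) -> pd.DataFrame:
    """Binary membership (1/0, NaN when the defining covariate is missing)
    for each of the six pre-specified subgroups, keyed by participant."""
    p = participants

    def binary(series, true_value=True):
        out = pd.Series(np.nan, index=p.index, dtype=float)
        obs = series.notna()
        out[obs] = (series[obs] == true_value).astype(float)
        return out

    onset = pd.to_numeric(p["symptom_onset_hours_before_enrolment"], errors="coerce")
    age = pd.to_numeric(p["age_days"], errors="coerce")
    frame = pd.DataFrame({
        "participant_id": p["participant_id"],
        "age_lt6m": np.where(age.notna(), (age < AGE_CUTOFF_DAYS).astype(float), np.nan),
        "onset_48h": np.where(onset.notna(), (onset <= ONSET_CUTOFF_H).astype(float), np.nan),
        "eczema": binary(p["eczema"]),
        "family_atopy": binary(p["family_atopy"]),
        "hemisphere": binary(p["site_hemisphere"], "southern"),
        "delivery_mode": binary(p["delivery_mdi"]),
    })
    return frame


SUBGROUP_LEVELS = {
    "age_lt6m": ("age >= 6 months", "age < 6 months"),
    "onset_48h": ("onset > 48 h", "onset within 48 h"),
    "eczema": ("no eczema", "eczema"),
    "family_atopy": ("no family atopy", "family atopy"),
    "hemisphere": ("northern", "southern"),
    "delivery_mode": ("nebuliser", "MDI-s"),
}


@dataclass
class InteractionResult:
    subgroup: str
    prob_positive: float
    declaration: str                     # positive / negative / none
    interaction_hdi: tuple[float, float]
    per_level_rr: dict[str, float]
    cell_counts: pd.DataFrame
    draws: PosteriorDraws = field(repr=False, default=None)


class SubgroupError(ValueError):
    pass


def subgroup_interaction_analysis(
    data: pd.DataFrame,
    subgroup: str,
    priors: Optional[PriorSpec] = None,
    settings: Optional[McmcSettings] = None,
    threshold: float = 0.99,
    outcome: str = "y",
    diagnostics: bool = False,
) -> InteractionResult:
    """Fit the treatment-by-subgroup interaction model and apply the 99% rule.

    ``data`` must carry ``outcome``, ``arm`` and a binary ``group`` column for
    the subgroup (rows with missing membership are excluded from this model
    only).
    """
    df = data[data["group"].notna()].copy()
    df["group"] = df["group"].astype(float)
    cells = df.groupby(["arm", "group"], observed=True)[outcome].count().unstack(fill_value=0)
    if cells.size < 4 or (cells.to_numpy() == 0).any():
        raise SubgroupError(
            f"empty treatment-by-subgroup cell for {subgroup!r}; cell counts:\n{cells}"
        )
    fit = fit_rr_model(df, priors, settings, structure="interaction",
                       outcome=outcome, diagnostics=diagnostics)
    delta = fit.flat("delta_interaction")
    prob_pos = float(np.mean(delta > 0))
    if prob_pos > threshold:
        declaration = "positive"
    elif (1 - prob_pos) > threshold:
        declaration = "negative"
    else:
        declaration = "none"
    theta = fit.theta
    lo, hi = hdi(delta)
    levels = SUBGROUP_LEVELS.get(subgroup, ("level0", "level1"))
    per_level = {
        levels[0]: float(np.exp(theta).mean()),
        levels[1]: float(np.exp(theta + delta).mean()),
    }
    return InteractionResult(subgroup, prob_pos, declaration, (lo, hi),
                             per_level, cells, fit)


def run_all_subgroups(
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    settings: Optional[McmcSettings] = None,
    outcome: str = "primary_hosp_7d",
) -> dict[str, InteractionResult]:
    members = classify_subgroups(participants)
    base = participants[["participant_id", "arm"]].merge(
        outcomes[["participant_id", outcome, f"missing_{outcome}"]], on="participant_id")
    base = base[~base[f"missing_{outcome}"]]
    results = {}
    for sg in SUBGROUP_IDS:
        df = base.merge(members[["participant_id", sg]], on="participant_id")
        df = df.rename(columns={sg: "group", outcome: "y"})
        df["y"] = df["y"].astype(int)
        results[sg] = subgroup_interaction_analysis(df, sg, priors, settings)
    return results


# --------------------------------------------------------------------------- #
# risk model and strata
# --------------------------------------------------------------------------- #

@dataclass
class RiskModel:
    covariates: list[str]
    coefficients: dict[str, float]
    intercept: float
    penalty_c: float
    converged: bool
    _pipeline: object = field(repr=False, default=None)
    _columns: list[str] = field(repr=False, default_factory=list)

    def predict_risk(self, participants: pd.DataFrame) -> np.ndarray:
        X = _risk_design(participants, self.covariates)
        X = X.reindex(columns=self._columns, fill_value=0.0)
        return self._pipeline.predict_proba(X.to_numpy())[:, 1]


def _risk_design(participants: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for c in covariates:
        s = participants[c]
        if s.dtype == object or str(s.dtype) == "category":
            dummies = pd.get_dummies(s, prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols[dc] = dummies[dc].astype(float)
        else:
            cols[c] = pd.to_numeric(s, errors="coerce").astype(float)
    X = pd.DataFrame(cols, index=participants.index)
    return X.fillna(X.mean())


def fit_risk_model(
    data: pd.DataFrame,
    covariates=RISK_MODEL_COVARIATES,
    outcome: str = "primary_hosp_7d",
    penalty_c: float = 100.0,
) -> RiskModel:
    """Penalised logistic hospitalisation-risk model, blind to treatment.

    A weak ridge penalty stabilises the fit; on complete separation the
    penalty is tightened (smaller C) with a warning.  The treatment arm never
    enters the design matrix.
    """
    if "arm" in covariates:
        raise ValueError("treatment assignment must not enter the risk model")
    X = _risk_design(data, covariates)
    mean, sd = X.mean(), X.std().replace(0, 1.0)
    Xs = (X - mean) / sd
    y = data[outcome].astype(int).to_numpy()
    c = penalty_c
    for _ in range(4):
        model = LogisticRegression(penalty="l2", C=c, max_iter=2000, solver="lbfgs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs.to_numpy(), y)
        if np.all(np.abs(model.coef_) < 15):
            break
        warnings.warn(f"risk model near separation; tightening ridge penalty (C={c/10})",
                      stacklevel=2)
        c /= 10

    class _Pipe:
        def __init__(self, m, mu, s):
            self.m, self.mu, self.s = m, mu.to_numpy(), s.to_numpy()

        def predict_proba(self, A):
            return self.m.predict_proba((A - self.mu) / self.s)

    rm = RiskModel(
        covariates=list(covariates),
        coefficients=dict(zip(Xs.columns, model.coef_[0] / sd.to_numpy())),
        intercept=float(model.intercept_[0] - np.sum(model.coef_[0] * (mean / sd).to_numpy())),
        penalty_c=c, converged=True,
        _pipeline=_Pipe(model, mean, sd), _columns=list(X.columns),
    )
    return rm


def make_risk_strata(predicted_risks: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Assign decile strata of predicted risk (stable order tie-break).

    Returns (assignments in 0..k-1, boundaries of length k+1).  With fewer
    distinct risk values than strata the empty strata are merged with a
    warning.
    """
    r = np.asarray(predicted_risks, dtype=float)
    n = r.size
    if n < k:
        raise ValueError(f"need at least k={k} participants to form {k} strata")
    order = np.lexsort((np.arange(n), r))  # stable: ties keep participant order
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    assign = np.empty(n, dtype=int)
    assign[order] = np.repeat(np.arange(k), sizes)
    bounds = np.concatenate([[r.min()], np.quantile(r, np.arange(1, k) / k), [r.max()]])
    if np.unique(r).size < k:
        warnings.warn(
            f"only {np.unique(r).size} distinct risk values for {k} strata; "
            "adjacent strata are effectively merged", stacklevel=2)
    return assign, bounds


@dataclass
class StrataResult:
    boundaries: np.ndarray
    table: pd.DataFrame  # stratum, n_placebo, n_epidex, events_*, median_rr, hdi, estimable


def stratum_treatment_effects(
    data: pd.DataFrame,
    strata: np.ndarray,
    priors: Optional[PriorSpec] = None,
    settings: Optional[McmcSettings] = None,
    outcome: str = "y",
    method: str = "mcmc",
) -> StrataResult:
    """Per-stratum relative-risk posteriors (median RR and 95% HDI).

    Within a stratum the model is the unadjusted two-arm relative-risk
    regression (cells are too small to support site adjustment).  Strata with
    only one arm represented are reported as inestimable, never dropped.
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    df = data.copy()
    df["_stratum"] = strata
    rows = []
    for s in range(int(strata.max()) + 1):
        sub = df[df["_stratum"] == s]
        arm_codes = sub["arm"].map({"placebo": 0, "epidex": 1}) if sub["arm"].dtype == object \
            else sub["arm"]
        n0, n1 = int((arm_codes == 0).sum()), int((arm_codes == 1).sum())
        e0 = int(sub.loc[arm_codes == 0, outcome].sum())
        e1 = int(sub.loc[arm_codes == 1, outcome].sum())
        row = {"stratum": s, "n_placebo": n0, "n_epidex": n1,
               "events_placebo": e0, "events_epidex": e1}
        if n0 == 0 or n1 == 0:
            row.update({"median_rr": np.nan, "rr_lo": np.nan, "rr_hi": np.nan,
                        "estimable": False})
        else:
            fit = fit_rr_model(
                sub, priors, settings.model_copy(update={"seed": settings.seed + s}),
                structure="two_arm", outcome=outcome, method=method, diagnostics=False)
            rr = np.exp(fit.theta)
            lo, hi = hdi(rr)
            row.update({"median_rr": float(np.median(rr)), "rr_lo": lo, "rr_hi": hi,
                        "estimable": True,
                        "prob_superiority": prob_superiority(fit)})
        rows.append(row)
    table = pd.DataFrame(rows)
    return StrataResult(boundaries=None, table=table)


def hte_analysis(
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    k: int = 10,
    priors: Optional[PriorSpec] = None,
    settings: Optional[McmcSettings] = None,
    outcome: str = "primary_hosp_7d",
    method: str = "mcmc",
) -> tuple[RiskModel, StrataResult]:
    """Full risk-stratified HTE analysis on the observed-outcome population."""
    df = participants.merge(
        outcomes[["participant_id", outcome, f"missing_{outcome}"]], on="participant_id")
    df = df[~df[f"missing_{outcome}"]].reset_index(drop=True)
    df["y"] = df[outcome].astype(int)
    rm = fit_risk_model(df, outcome="y")
    risks = rm.predict_risk(df)
    assign, bounds = make_risk_strata(risks, k)
    res = stratum_treatment_effects(df, assign, priors, settings, method=method)
    res.boundaries = bounds
    return rm, res
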