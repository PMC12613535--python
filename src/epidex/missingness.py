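"""Missing-data descriptives, the 5% complete-case gate, and the joint
Bayesian missingness-and-outcome model for partially observed covariates.

Policy encoded here: with less than 5% of a variable missing, complete-case
analysis proceeds; at 5% or more the baseline characteristics of
participants with and without missing values are compared descriptively to
judge whether complete-case analysis remains defensible, and if it does not,
a joint model of the missingness mechanism and the outcome is fitted.
Missing *outcomes* are never modelled or imputed — they only reduce the
analysed set and are reported descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._mcmc import binom_loglik_cells
from .config import McmcSettings, PriorSpec
from .inference import PosteriorDraws

GATE_THRESHOLD = 0.05


class MissingnessError(ValueError):
    pass


def gate_decision(proportion: float) -> str:
    """Complete-case below 5%; at or above, evaluate before deciding.

    A pure threshold function of the missing proportion: exactly 5% routes to
    evaluation ("below 5%" read strictly).
    """
    if not 0 <= proportion <= 1:
        raise MissingnessError("proportion must lie in [0, 1]")
    return "complete_case" if proportion < GATE_THRESHOLD else "evaluate_then_decide"


@dataclass
class MissingnessReport:
    by_variable: pd.DataFrame     # variable, arm, n, n_missing, proportion
    overall: pd.DataFrame         # variable, proportion, gate
    gates: dict[str, str] = field(default_factory=dict)


def missingness_report(
    participants: pd.DataFrame,
    outcomes: Optional[pd.DataFrame] = None,
    variables: Optional[list[str]] = None,
) -> MissingnessReport:
    """Per-variable, per-arm missing proportions and gate decisions.

    Denominators are randomised participants who did not withdraw consent.
    Outcome missingness comes from the derivation's ``missing_*`` flags.
    """
    base = participants[~participants["withdrawal"].fillna(False).astype(bool)].copy()
    if variables is None:
        variables = [c for c in base.columns
                     if c not in ("participant_id", "arm", "withdrawal", "withdrawal_reason")]
    rows = []
    for var in variables:
        for arm, g in base.groupby("arm"):
            n_missing = int(g[var].isna().sum())
            rows.append({"variable": var, "arm": arm, "n": len(g),
                         "n_missing": n_missing, "proportion": n_missing / len(g)})
    if outcomes is not None:
        oc = outcomes.merge(base[["participant_id", "arm"]], on="participant_id")
        for col in [c for c in outcomes.columns if c.startswith("missing_")]:
            var = col.removeprefix("missing_")
            for arm, g in oc.groupby("arm"):
                n_missing = int(g[col].sum())
                rows.append({"variable": var, "arm": arm, "n": len(g),
                             "n_missing": n_missing, "proportion": n_missing / len(g)})
    by_var = pd.DataFrame(rows)
    overall = (by_var.groupby("variable")[["n", "n_missing"]].sum().reset_index())
    overall["proportion"] = overall["n_missing"] / overall["n"]
    overall["gate"] = overall["proportion"].map(gate_decision)
    gates = dict(zip(overall["variable"], overall["gate"]))
    return MissingnessReport(by_var, overall, gates)


def _smd(observed: pd.Series, missing_group: pd.Series) -> float:
    """Standardised mean difference between the two groups of a covariate."""
    a = pd.to_numeric(observed, errors="coerce").dropna()
    b = pd.to_numeric(missing_group, errors="coerce").dropna()
    if len(a) < 2 or len(b) < 2:
        return np.nan
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
    if pooled == 0:
        return 0.0
    return float((b.mean() - a.mean()) / pooled)


def compare_baseline_by_missingness(
    participants: pd.DataFrame,
    variable: str,
    baseline_vars: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Descriptive baseline comparison, with-missing vs fully observed.

    Summaries plus standardised mean differences only — no hypothesis tests.
    SMD magnitudes above 0.2 are flagged as noteworthy imbalance.
    """
    miss = participants[variable].isna()
    if miss.sum() == 0 or (~miss).sum() == 0:
        raise MissingnessError(
            f"comparison needs at least one missing and one observed value of {variable!r}"
        )
    if baseline_vars is None:
        numeric = participants.select_dtypes(include=[np.number, bool]).columns
        baseline_vars = [c for c in numeric if c != variable]
    rows = []
    for var in baseline_vars:
        obs = pd.to_numeric(participants.loc[~miss, var], errors="coerce")
        mis = pd.to_numeric(participants.loc[miss, var], errors="coerce")
        smd = _smd(obs, mis)
        rows.append({
            "baseline_variable": var,
            "mean_observed": float(obs.mean()), "mean_missing_group": float(mis.mean()),
            "smd": smd, "flagged": bool(abs(smd) > 0.2) if np.isfinite(smd) else False,
        })
    return pd.DataFrame(rows)


def fit_joint_missingness_model(
    data: pd.DataFrame,
    covariate: str,
    priors: Optional[PriorSpec] = None,
    settings: Optional[McmcSettings] = None,
    missingness_on_outcome: bool = True,
) -> PosteriorDraws:
    """Joint Bayesian model of outcome, covariate and missingness mechanism.

    Selection-model factorisation for a partially observed binary covariate x:

      * outcome:      log P(y=1) = beta0 + theta*arm + beta_x*x  (log link)
      * covariate:    x ~ Bernoulli(pi), conjugate Beta(1,1) prior
      * missingness:  logit P(x missing) = alpha0 + alpha_x*x [+ alpha_y*y]

    Missing x values are imputed inside the Gibbs sweep from their full
    conditional, so the treatment effect ``theta`` is estimated on the same
    scale as the plain relative-risk fit.  The covariate must be partially
    observed; the outcome must be fully observed.
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()
    df = data.copy()
    arm = df["arm"].map({"placebo": 0, "epidex": 1}).to_numpy() if df["arm"].dtype == object \
        else df["arm"].to_numpy(int)
    y = df["y"].to_numpy(int)
    x_obs = pd.to_numeric(df[covariate], errors="coerce").to_numpy(float)
    miss = np.isnan(x_obs)
    if miss.all():
        raise MissingnessError(f"covariate {covariate!r} is fully missing")
    if not miss.any():  # nothing to model jointly: collapses to the outcome model
        miss = np.zeros(len(df), bool)

    # pattern collapse: all subjects sharing (arm, y, miss, x-if-observed)
    # behave identically in every update
    x_filled = np.where(miss, 0, x_obs).astype(int)
    pat = arm * 8 + y * 4 + miss.astype(int) * 2 + x_filled
    pat_ids, pat_index, pat_counts = np.unique(pat, return_inverse=True, return_counts=True)
    P = len(pat_ids)
    p_arm = (pat_ids // 8).astype(float)
    p_y = ((pat_ids // 4) % 2).astype(float)
    p_miss = ((pat_ids // 2) % 2).astype(bool)
    p_x0 = (pat_ids % 2).astype(float)

    from scipy.special import expit

    rng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(41,)))
    csd = priors.coefficient_sd
    names = ["beta0", "theta", "beta_x", "alpha0", "alpha_x"] + (
        ["alpha_y"] if missingness_on_outcome else [])
    n_alpha = 2 + int(missingness_on_outcome)
    out = {nm: np.empty((settings.n_chains, settings.n_draws)) for nm in names}
    out["pi"] = np.empty((settings.n_chains, settings.n_draws))

    def outcome_ll_per_pattern(beta, x_cnt1, cnt):
        """Log-lik summed within pattern, given count with x=1 per pattern."""
        b0, th, bx = beta
        ll = np.zeros(P)
        for xv in (0.0, 1.0):
            eta = b0 + th * p_arm + bx * xv
            npat = x_cnt1 if xv == 1.0 else cnt - x_cnt1
            k = npat * p_y
            lterm = binom_loglik_cells(eta, k, npat)
            lterm = np.where(npat > 0, lterm, 0.0)
            ll += lterm
        return ll

    for chain in range(settings.n_chains):
        crng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(41, chain)))
        beta = np.array([np.log(max(y.mean(), 1e-3)), 0.0, 0.0])
        alpha = np.zeros(n_alpha)
        pi = 0.5
        # per-pattern count of x=1 among its members (imputed for missing)
        cnt = pat_counts.astype(float)
        x_cnt1 = np.where(p_miss, np.round(cnt * 0.5), p_x0 * cnt)
        step_b = np.full(3, 0.1)
        step_a = np.full(n_alpha, 0.3)
        cur_oll = outcome_ll_per_pattern(beta, x_cnt1, cnt).sum()

        for t in range(settings.n_warmup + settings.n_draws):
            gamma = (t + 1) ** -0.6 if t < settings.n_warmup else 0.0
            # --- outcome-model coefficients (RWM) ---
            for j in range(3):
                prop = beta.copy()
                prop[j] += step_b[j] * crng.standard_normal()
                ll = outcome_ll_per_pattern(prop, x_cnt1, cnt).sum()
                lp = -0.5 * (prop[1:] ** 2).sum() / csd**2
                lp0 = -0.5 * (beta[1:] ** 2).sum() / csd**2
                acc = 0.0
                if np.isfinite(ll):
                    acc = min(1.0, np.exp(min(ll + lp - cur_oll - lp0, 0.0)))
                    if crng.random() < acc:
                        beta, cur_oll = prop, ll
                if gamma:
                    step_b[j] *= np.exp(gamma * (acc - settings.target_acceptance))

            # --- covariate prevalence (conjugate) ---
            n1 = x_cnt1.sum()
            pi = crng.beta(1 + n1, 1 + cnt.sum() - n1)

            # --- missingness-model coefficients (RWM, Bernoulli-logit lik) ---
            def miss_ll(al):
                ll = 0.0
                for xv in (0.0, 1.0):
                    eta = al[0] + al[1] * xv + (al[2] * p_y if n_alpha == 3 else 0.0)
                    npat = x_cnt1 if xv == 1.0 else cnt - x_cnt1
                    pm = expit(eta)
                    ll += np.sum(npat * np.where(p_miss, np.log(pm + 1e-300),
                                                 np.log(1 - pm + 1e-300)))
                return ll

            cur_mll = miss_ll(alpha)
            for j in range(n_alpha):
                prop = alpha.copy()
                prop[j] += step_a[j] * crng.standard_normal()
                ll = miss_ll(prop)
                lp = -0.5 * (prop**2).sum() / 10**2
                lp0 = -0.5 * (alpha**2).sum() / 10**2
                acc = min(1.0, np.exp(min(ll + lp - cur_mll - lp0, 0.0)))
                if crng.random() < acc:
                    alpha, cur_mll = prop, ll
                if gamma:
                    step_a[j] *= np.exp(gamma * (acc - settings.target_acceptance))

            # --- impute missing covariate values (exact full conditional) ---
            b0, th, bx = beta
            for i in np.flatnonzero(p_miss):
                eta0 = b0 + th * p_arm[i]
                eta1 = eta0 + bx
                if eta1 >= 0 or eta0 >= 0:
                    continue  # keep previous imputation: proposal outside support
                ly0 = p_y[i] * eta0 + (1 - p_y[i]) * np.log1p(-np.exp(eta0))
                ly1 = p_y[i] * eta1 + (1 - p_y[i]) * np.log1p(-np.exp(eta1))
                lm0 = np.log(expit(alpha[0] + (alpha[2] * p_y[i] if n_alpha == 3 else 0.0)) + 1e-300)
                lm1 = np.log(expit(alpha[0] + alpha[1]
                                   + (alpha[2] * p_y[i] if n_alpha == 3 else 0.0)) + 1e-300)
                w1 = pi * np.exp(ly1 + lm1)
                w0 = (1 - pi) * np.exp(ly0 + lm0)
                prob1 = w1 / (w1 + w0) if (w1 + w0) > 0 else 0.5
                x_cnt1[i] = crng.binomial(int(pat_counts[i]), prob1)
            cur_oll = outcome_ll_per_pattern(beta, x_cnt1, cnt).sum()

            if t >= settings.n_warmup:
                i0 = t - settings.n_warmup
                for j, nm in enumerate(["beta0", "theta", "beta_x"]):
                    out[nm][chain, i0] = beta[j]
                for j in range(n_alpha):
                    out[names[3 + j]][chain, i0] = alpha[j]
                out["pi"][chain, i0] = pi

    return PosteriorDraws(out, "joint_missingness", "mcmc",
                          meta={"covariate": covariate, "n": int(len(df)),
                                "n_missing": int(miss.sum())})
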