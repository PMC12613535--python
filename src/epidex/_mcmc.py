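"""Adaptive random-walk Metropolis-within-Gibbs sampler.

Purpose-built for the small generalised-linear models this pipeline fits:
log-link binomial (relative-risk) regression with an exact handling of the
p <= 1 support constraint, piecewise-exponential (Poisson) hazard models, and
location-scale models for costs.  Data enter as collapsed sufficient
statistics (one row per covariate pattern), so a likelihood evaluation costs
a handful of vector operations regardless of sample size.

Fixed effects are updated one scalar at a time; random effects are updated as
a vector block with elementwise accept/reject, which is valid because they
are conditionally independent given everything else.  Proposal scales adapt
during warmup by a decaying Robbins-Monro rule targeting the configured
acceptance rate, and are frozen afterwards.
"""

from __future__ import annotations

import numpy as np

TARGET_VECTOR_ACCEPT = 0.44


def binom_loglik_cells(eta: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-cell log-likelihood of a log-link binomial model; -inf where p >= 1."""
    if (eta < 0).all():  # common path: inside the support everywhere
        return k * eta + (n - k) * np.log1p(-np.exp(eta))
    out = np.full(eta.shape, -np.inf)
    ok = eta < 0
    if ok.any():
        e, kk, nn = eta[ok], k[ok], n[ok]
        out[ok] = kk * e + (nn - kk) * np.log1p(-np.exp(e))
    return out


def poisson_loglik_cells(eta: np.ndarray, d: np.ndarray, expo: np.ndarray) -> np.ndarray:
    """Per-cell log-likelihood of a log-link Poisson (piecewise-exponential) model."""
    return d * eta - expo * np.exp(eta)


def _halfnormal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf


def sample_glm(
    loglik_cells,
    X: np.ndarray,
    re_idx: np.ndarray | None,
    logprior_beta,
    *,
    n_chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_acceptance: float = 0.44,
    re_scale: float = 1.0,
    init_beta: np.ndarray,
    param_names: list[str],
    re_name: str = "site",
) -> dict[str, np.ndarray]:
    """Sample the posterior of ``eta = X @ beta (+ u[re_idx])``.

    ``loglik_cells(eta)`` returns per-cell log-likelihood contributions;
    ``logprior_beta(beta)`` the joint log-prior of the fixed effects (may be
    improper).  When ``re_idx`` is given, random effects ``u ~ N(0, sigma^2)``
    with a half-normal(``re_scale``) prior on sigma are added.

    Returns draws with shape ``(n_chains, n_draws)`` per scalar parameter
    (random effects as ``{re_name}[j]``, their SD as ``sigma_{re_name}``).
    """
    p = X.shape[1]
    m = 0 if re_idx is None else int(re_idx.max()) + 1
    names = list(param_names)
    assert len(names) == p
    out = {nm: np.empty((n_chains, n_draws)) for nm in names}
    if m:
        for j in range(m):
            out[f"{re_name}[{j}]"] = np.empty((n_chains, n_draws))
        out[f"sigma_{re_name}"] = np.empty((n_chains, n_draws))

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(chain,)))
        beta = init_beta + 0.01 * rng.standard_normal(p)
        u = np.zeros(m)
        log_sigma = np.log(0.5 * re_scale)
        eta = X @ beta + (u[re_idx] if m else 0.0)
        # back off until the chain starts inside the support
        for _ in range(200):
            ll = loglik_cells(eta)
            if np.isfinite(ll.sum()):
                break
            beta[0] -= 0.2
            eta = X @ beta + (u[re_idx] if m else 0.0)
        cur_ll = ll.sum()
        cur_lp = logprior_beta(beta)
        step = np.full(p, 0.1)
        step_u = np.full(m, 0.2) if m else None
        step_s = 0.3

        for t in range(n_warmup + n_draws):
            gamma = (t + 1) ** -0.6 if t < n_warmup else 0.0
            # fixed effects, scalar at a time
            for j in range(p):
                prop = beta.copy()
                prop[j] += step[j] * rng.standard_normal()
                eta_prop = eta + X[:, j] * (prop[j] - beta[j])
                ll_prop = loglik_cells(eta_prop).sum()
                acc = 0.0
                if np.isfinite(ll_prop):
                    lp_prop = logprior_beta(prop)
                    log_r = (ll_prop + lp_prop) - (cur_ll + cur_lp)
                    acc = min(1.0, np.exp(min(log_r, 0.0)))
                    if rng.random() < acc:
                        beta, eta, cur_ll, cur_lp = prop, eta_prop, ll_prop, lp_prop
                if gamma:
                    step[j] *= np.exp(gamma * (acc - target_acceptance))
            # random effects: conditionally independent, elementwise MH
            if m:
                sigma = np.exp(log_sigma)
                u_prop = u + step_u * rng.standard_normal(m)
                ll_cells = loglik_cells(eta)
                eta_prop = eta + (u_prop - u)[re_idx]
                ll_cells_prop = loglik_cells(eta_prop)
                d_ll = np.bincount(re_idx, ll_cells_prop - ll_cells, minlength=m)
                d_ll += 0.5 * (u**2 - u_prop**2) / sigma**2
                acc_u = np.exp(np.minimum(d_ll, 0.0))
                take = rng.random(m) < acc_u
                u = np.where(take, u_prop, u)
                eta = X @ beta + u[re_idx]
                cur_ll = loglik_cells(eta).sum()
                if gamma:
                    step_u *= np.exp(gamma * (acc_u - TARGET_VECTOR_ACCEPT))
                # random-effect SD on the log scale (half-normal prior + Jacobian)
                ls_prop = np.clip(log_sigma + step_s * rng.standard_normal(), -20.0, 20.0)
                s0, s1 = np.exp(log_sigma), np.exp(ls_prop)
                log_r = (
                    -m * ls_prop - 0.5 * (u**2).sum() / s1**2 + _halfnormal_logpdf(s1, re_scale) + ls_prop
                ) - (
                    -m * log_sigma - 0.5 * (u**2).sum() / s0**2 + _halfnormal_logpdf(s0, re_scale) + log_sigma
                )
                acc = min(1.0, np.exp(min(log_r, 0.0)))
                if rng.random() < acc:
                    log_sigma = ls_prop
                if gamma:
                    step_s *= np.exp(gamma * (acc - target_acceptance))
            if t >= n_warmup:
                i = t - n_warmup
                for j, nm in enumerate(names):
                    out[nm][chain, i] = beta[j]
                if m:
                    for j in range(m):
                        out[f"{re_name}[{j}]"][chain, i] = u[j]
                    out[f"sigma_{re_name}"][chain, i] = np.exp(log_sigma)
    return out
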