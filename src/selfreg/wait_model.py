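"""Random-effects tobit model of censored preschool wait times and the
rank-normalized delay (RND) score built on it.

The delay-of-gratification experiments recorded how long each child
waited for a larger reward, censored at a limit (typically 900 s), under
one of many experimental conditions whose difficulty varied widely and
whose per-condition sample sizes ranged from a handful to well over a
hundred.  The model here treats the latent log wait time as

    y*_gi = alpha + beta_age * age_gi + beta_male * male_gi + eta_g + eps_gi

with a condition-level random effect eta_g ~ N(0, sigma_eta^2) and an
individual error eps_gi ~ N(0, sigma_eps^2).  Observed waits are
min(exp(y*), censor).  Estimation is by maximum likelihood with the
random effect integrated out by adaptive Gauss–Hermite quadrature;
censored records contribute the upper-tail probability, uncensored
records the normal density, of the latent log wait.

From the fit, each child's expected log wait (fixed part plus the
empirical-Bayes posterior mean of their condition's effect) is
subtracted from their actual — or, when censored, conditionally
imputed — log wait, and the deviations are rank-normalized into RND.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import log_ndtr, logsumexp, ndtri

from .transforms import rank_inverse_normal

logger = logging.getLogger(__name__)

__all__ = [
    "WaitRecord",
    "TobitParams",
    "TobitREFit",
    "RNDScores",
    "EstimationError",
    "fit_tobit_re",
    "expected_ln_wait",
    "impute_censored_ln_wait",
    "compute_rnd",
]

#: Waits recorded as 0 s (reward taken immediately) are floored here
#: before taking logs; below any plausibly distinguishable reaction time.
MIN_WAIT_SECONDS = 1.0

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    """Maximum-likelihood estimation failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class WaitRecord:
    """One child's first delay-task observation."""

    participant: str
    condition: str
    age_months: float
    male: int
    wait_seconds: float
    censored: bool


@dataclass(frozen=True)
class TobitParams:
    """Parameters of the censored log-normal wait-time model.

    ``alpha`` is the intercept in log-seconds; ``beta_age`` the effect of
    one month of age; ``beta_male`` the male shift; ``sigma_eta`` the SD
    of the condition random effect; ``sigma_eps`` the individual error
    SD; ``censor_seconds`` the wait limit.
    """

    alpha: float
    beta_age: float
    beta_male: float
    sigma_eta: float
    sigma_eps: float
    censor_seconds: float = 900.0

    def __post_init__(self):
        if self.sigma_eta < 0:
            raise ValueError("sigma_eta must be >= 0")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be > 0")
        if self.censor_seconds <= 0:
            raise ValueError("censor_seconds must be > 0")

    def fixed_part(self, age_months, male):
        return self.alpha + self.beta_age * np.asarray(age_months) + self.beta_male * np.asarray(male)


@dataclass
class TobitREFit:
    """Maximum-likelihood fit of the random-effects tobit model."""

    params: TobitParams
    se: dict[str, float]
    loglik: float
    eb_eta: pd.Series          # posterior mean of eta_g per condition
    eb_eta_sd: pd.Series       # posterior SD of eta_g per condition
    converged: bool
    n_obs: int
    n_conditions: int
    n_quad: int
    diagnostics: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Parameter table (estimate, SE) in the conventional layout."""
        rows = {
            "beta_age": self.params.beta_age,
            "beta_male": self.params.beta_male,
            "alpha": self.params.alpha,
            "sigma_eps": self.params.sigma_eps,
            "sigma_eta": self.params.sigma_eta,
        }
        return pd.DataFrame(
            {"estimate": rows, "se": {k: self.se.get(k, np.nan) for k in rows}}
        )


# --------------------------------------------------------------------------
# data preparation

_REQUIRED_COLS = ["participant", "condition", "age_months", "male", "wait_seconds", "censored"]


def _prepare(records: pd.DataFrame, censor_seconds: float) -> pd.DataFrame:
    if isinstance(records, (list, tuple)):
        records = pd.DataFrame([r.__dict__ if isinstance(r, WaitRecord) else r for r in records])
    missing = [c for c in _REQUIRED_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"wait records missing columns: {missing}")
    df = records.copy()
    if df["participant"].duplicated().any():
        ndup = int(df["participant"].duplicated().sum())
        logger.warning("dropping %d repeat delay-task records; keeping each child's first", ndup)
        df = df.drop_duplicates("participant", keep="first")
    if (df["wait_seconds"] <= 0).any():
        df["wait_seconds"] = df["wait_seconds"].clip(lower=MIN_WAIT_SECONDS)
    bad = df["censored"].astype(bool) & (df["wait_seconds"] != censor_seconds)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} records flagged censored but wait differs from the "
            f"{censor_seconds:g} s limit"
        )
    return df.sort_values("condition", kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature

class _Quadrature:
    """Workspace for the grouped marginal log-likelihood."""

    def __init__(self, df: pd.DataFrame, censor_seconds: float, n_quad: int):
        self.y = np.log(df["wait_seconds"].to_numpy(float))
        self.cens = df["censored"].to_numpy(bool)
        self.age = df["age_months"].to_numpy(float)
        self.male = df["male"].to_numpy(float)
        self.log_c = math.log(censor_seconds)
        codes, self.conditions = pd.factorize(df["condition"], sort=True)
        self.g = codes
        self.n_groups = len(self.conditions)
        self.starts = np.searchsorted(codes, np.arange(self.n_groups))
        self.n_unc_per_group = np.bincount(codes, weights=(~self.cens).astype(float),
                                           minlength=self.n_groups)
        x, w = hermgauss(n_quad)
        self.nodes = x
        self.logw = np.log(w)

    # r: "reduced" response per record. For uncensored records r = y - xb;
    # for censored records r = log(c) - xb, and the contribution is
    # log Phi((eta - r)/sigma_eps).
    def _reduced(self, alpha, ba, bm):
        xb = alpha + ba * self.age + bm * self.male
        r = np.where(self.cens, self.log_c, self.y) - xb
        return r

    def _group_sum(self, values):
        return np.add.reduceat(values, self.starts)

    def _mode_and_scale(self, r, sigma_eta, sigma_eps, tol=1e-10, max_iter=60):
        """Laplace mode m_g and curvature scale s_g of the per-group
        integrand, by a vectorized Newton iteration (the integrand is
        strictly log-concave in eta)."""
        inv_se2 = 1.0 / sigma_eps**2
        m = np.zeros(self.n_groups)
        unc = ~self.cens
        r_unc = np.where(unc, r, 0.0)
        sum_r_unc = self._group_sum(r_unc)
        for _ in range(max_iter):
            eta = m[self.g]
            z = (eta - r) / sigma_eps
            lam = np.exp(stats.norm.logpdf(z) - log_ndtr(z))
            # lam*(z+lam) is positive by log-concavity; clamp the
            # floating-point cancellation that can flip it in the far tail
            curv = np.maximum(lam * (z + lam), 0.0)
            grad_cens = np.where(self.cens, lam / sigma_eps, 0.0)
            hess_cens = np.where(self.cens, curv * inv_se2, 0.0)
            grad = (-m / sigma_eta**2
                    + (sum_r_unc - self.n_unc_per_group * m) * inv_se2
                    + self._group_sum(grad_cens))
            hess = (-1.0 / sigma_eta**2
                    - self.n_unc_per_group * inv_se2
                    - self._group_sum(hess_cens))
            step = grad / hess
            step = np.where(np.isfinite(step), np.clip(step, -10.0, 10.0), 0.0)
            m = m - step
            if np.max(np.abs(step)) < tol:
                break
        s = 1.0 / np.sqrt(np.maximum(-hess, 1e-12))
        return m, s

    def _node_h(self, r, sigma_eta, sigma_eps, m, s):
        """h(eta_gk) = log prior + sum_i log L_i at the adapted nodes;
        returns (eta_nodes (G,K), h (G,K))."""
        eta_nodes = m[:, None] + math.sqrt(2.0) * s[:, None] * self.nodes[None, :]
        eta_rec = eta_nodes[self.g]                       # (n, K)
        z = (eta_rec - r[:, None]) / sigma_eps
        l_unc = -math.log(sigma_eps) - _LOG_SQRT_2PI - 0.5 * z**2
        l_cen = log_ndtr(z)
        rec = np.where(self.cens[:, None], l_cen, l_unc)
        group_ll = np.add.reduceat(rec, self.starts, axis=0)  # (G, K)
        log_prior = (-0.5 * (eta_nodes / sigma_eta) ** 2
                     - math.log(sigma_eta) - _LOG_SQRT_2PI)
        return eta_nodes, group_ll + log_prior

    def loglik(self, alpha, ba, bm, sigma_eta, sigma_eps):
        r = self._reduced(alpha, ba, bm)
        m, s = self._mode_and_scale(r, sigma_eta, sigma_eps)
        _, h = self._node_h(r, sigma_eta, sigma_eps, m, s)
        per_group = logsumexp(h + self.nodes[None, :] ** 2 + self.logw[None, :], axis=1)
        per_group = per_group + 0.5 * math.log(2.0) + np.log(s)
        return float(per_group.sum())

    def loglik_no_re(self, alpha, ba, bm, sigma_eps):
        """Plain tobit likelihood with sigma_eta fixed at zero."""
        r = self._reduced(alpha, ba, bm)
        z = -r / sigma_eps
        l_unc = -math.log(sigma_eps) - _LOG_SQRT_2PI - 0.5 * z**2
        l_cen = log_ndtr(z)
        return float(np.where(self.cens, l_cen, l_unc).sum())

    def posterior_eta(self, alpha, ba, bm, sigma_eta, sigma_eps):
        """Posterior mean and SD of eta_g per group at fixed parameters."""
        r = self._reduced(alpha, ba, bm)
        m, s = self._mode_and_scale(r, sigma_eta, sigma_eps)
        eta_nodes, h = self._node_h(r, sigma_eta, sigma_eps, m, s)
        logw = h + self.nodes[None, :] ** 2 + self.logw[None, :]
        logw = logw - logsumexp(logw, axis=1, keepdims=True)
        w = np.exp(logw)
        mean = (w * eta_nodes).sum(axis=1)
        var = (w * eta_nodes**2).sum(axis=1) - mean**2
        return mean, np.sqrt(np.clip(var, 0.0, None))


def _moment_start(quad: _Quadrature) -> np.ndarray:
    """Crude starting values: OLS of log wait (censored records at the
    limit) on age and sex; error split into between/within components."""
    X = np.column_stack([np.ones_like(quad.age), quad.age, quad.male])
    y = np.where(quad.cens, quad.log_c, quad.y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    group_means = np.add.reduceat(resid, quad.starts) / np.add.reduceat(
        np.ones_like(resid), quad.starts
    )
    s_eta = max(float(np.std(group_means)), 0.1)
    s_eps = max(float(np.std(resid)), 0.2)
    # censoring shrinks the observed spread; inflate the within component
    return np.array([beta[0], beta[1], beta[2], math.log(s_eta), math.log(1.3 * s_eps)])


def fit_tobit_re(
    records: pd.DataFrame,
    censor_seconds: float = 900.0,
    n_quad: int = 21,
    n_starts: int = 3,
    fix_sigma_eta: float | None = None,
    compute_se: bool = True,
) -> TobitREFit:
    """Fit the random-effects tobit model of log wait time by maximum
    likelihood with adaptive Gauss–Hermite quadrature.

    Parameters
    ----------
    records
        Wait records (one row per child: participant, condition,
        age_months, male, wait_seconds, censored).  Repeat records per
        participant are dropped, keeping the first.
    censor_seconds
        The wait limit; censored records must sit exactly at it.
    n_quad
        Number of quadrature nodes (>= 21 recommended).
    n_starts
        Optimizer restarts from perturbed initializations; the best
        optimum is kept.
    fix_sigma_eta
        If 0.0, fits a plain tobit without the condition random effect
        (single-condition data requires this).
    compute_se
        Compute observed-information standard errors (numerical Hessian).

    Raises
    ------
    EstimationError
        On non-convergence, all-censored data ("no interior optimum"),
        or unidentified sigma_eta (fewer than two conditions).
    """
    df = _prepare(records, censor_seconds)
    if df["censored"].all():
        raise EstimationError(
            "no interior optimum: every observation is censored, the likelihood "
            "increases without bound in alpha",
            {"n_censored": int(df["censored"].sum()), "n_obs": len(df)},
        )
    n_cond = df["condition"].nunique()
    if fix_sigma_eta is None and n_cond < 2:
        raise EstimationError(
            "sigma_eta is not identified with a single condition; "
            "pass fix_sigma_eta=0.0 to fit a plain tobit",
            {"n_conditions": n_cond},
        )
    quad = _Quadrature(df, censor_seconds, n_quad)

    if fix_sigma_eta is not None:
        if fix_sigma_eta != 0.0:
            raise NotImplementedError("only fix_sigma_eta=0.0 is supported")
        return _fit_no_re(df, quad, censor_seconds, n_starts, compute_se)

    def negll(theta):
        a, ba, bm, lse_eta, lse_eps = theta
        return -quad.loglik(a, ba, bm, math.exp(lse_eta), math.exp(lse_eps))

    start0 = _moment_start(quad)
    perturb = np.array(
        [[0.0, 0.0, 0.0, 0.0, 0.0],
         [0.5, 0.0, 0.0, math.log(1.6), math.log(0.7)],
         [-0.5, 0.01, -0.2, math.log(0.6), math.log(1.4)]]
    )
    best = None
    bounds = [(-20, 20), (-2, 2), (-20, 20), (math.log(1e-4), math.log(50)),
              (math.log(1e-3), math.log(50))]
    for k in range(max(1, n_starts)):
        theta0 = start0 + perturb[k % len(perturb)]
        res = optimize.minimize(
            negll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
        )
        # prefer successful terminations; among equals take the lower
        # objective (line searches can fail harmlessly at the optimum)
        if (best is None
                or (res.success and not best.success)
                or (res.success == best.success and res.fun < best.fun - 1e-10)):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("likelihood optimization failed", {"result": str(best)})
    if not best.success and np.max(np.abs(best.jac)) > 1e-3:
        polish = optimize.minimize(
            negll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            best = polish
            best.jac = np.zeros_like(polish.x)
        else:
            raise EstimationError(
                f"optimizer did not converge: {best.message}",
                {"grad_norm": float(np.max(np.abs(best.jac))),
                 "loglik": -float(best.fun)},
            )
    a, ba, bm, lse_eta, lse_eps = best.x
    params = TobitParams(a, ba, bm, math.exp(lse_eta), math.exp(lse_eps), censor_seconds)
    converged = True

    se = _observed_info_se(
        lambda p: quad.loglik(*p),
        np.array([params.alpha, params.beta_age, params.beta_male,
                  params.sigma_eta, params.sigma_eps]),
    ) if compute_se else {}

    eb_mean, eb_sd = quad.posterior_eta(
        params.alpha, params.beta_age, params.beta_male, params.sigma_eta, params.sigma_eps
    )
    return TobitREFit(
        params=params,
        se=se,
        loglik=-float(best.fun),
        eb_eta=pd.Series(eb_mean, index=quad.conditions, name="eb_eta"),
        eb_eta_sd=pd.Series(eb_sd, index=quad.conditions, name="eb_eta_sd"),
        converged=converged,
        n_obs=len(df),
        n_conditions=n_cond,
        n_quad=n_quad,
        diagnostics={"grad_norm": float(np.max(np.abs(best.jac))), "n_starts": n_starts},
    )


def fit_at_params(
    records: pd.DataFrame, params: TobitParams, n_quad: int = 21
) -> TobitREFit:
    """Build a :class:`TobitREFit` at externally supplied parameter values
    (no estimation): evaluates the marginal likelihood and the
    empirical-Bayes condition effects treating ``params`` as the truth.

    Useful for prediction at published estimates and for simulation
    studies where the generating parameters are known.
    """
    df = _prepare(records, params.censor_seconds)
    quad = _Quadrature(df, params.censor_seconds, n_quad)
    args = (params.alpha, params.beta_age, params.beta_male,
            params.sigma_eta, params.sigma_eps)
    if params.sigma_eta == 0:
        ll = quad.loglik_no_re(params.alpha, params.beta_age, params.beta_male,
                               params.sigma_eps)
        eb = np.zeros(quad.n_groups)
        eb_sd = np.zeros(quad.n_groups)
    else:
        ll = quad.loglik(*args)
        eb, eb_sd = quad.posterior_eta(*args)
    return TobitREFit(
        params=params, se={}, loglik=ll,
        eb_eta=pd.Series(eb, index=quad.conditions, name="eb_eta"),
        eb_eta_sd=pd.Series(eb_sd, index=quad.conditions, name="eb_eta_sd"),
        converged=True, n_obs=len(df), n_conditions=quad.n_groups,
        n_quad=n_quad, diagnostics={"fixed_params": True},
    )


def _fit_no_re(df, quad, censor_seconds, n_starts, compute_se):
    def negll(theta):
        a, ba, bm, lse = theta
        return -quad.loglik_no_re(a, ba, bm, math.exp(lse))

    s0 = _moment_start(quad)
    theta0 = np.array([s0[0], s0[1], s0[2], s0[4]])
    best = None
    for k in range(max(1, n_starts)):
        t0 = theta0 + (k * 0.3) * np.array([1.0, 0.0, 0.0, -0.2])
        res = optimize.minimize(negll, t0, method="L-BFGS-B",
                                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    a, ba, bm, lse = best.x
    params = TobitParams(a, ba, bm, 0.0, math.exp(lse), censor_seconds)
    se = _observed_info_se(
        lambda p: quad.loglik_no_re(*p),
        np.array([a, ba, bm, math.exp(lse)]),
        names=["alpha", "beta_age", "beta_male", "sigma_eps"],
    ) if compute_se else {}
    conditions = quad.conditions
    zeros = pd.Series(np.zeros(len(conditions)), index=conditions)
    return TobitREFit(
        params=params, se=se, loglik=-float(best.fun),
        eb_eta=zeros.rename("eb_eta"), eb_eta_sd=zeros.rename("eb_eta_sd"),
        converged=bool(best.success), n_obs=len(df),
        n_conditions=len(conditions), n_quad=quad.nodes.size,
        diagnostics={"fixed_sigma_eta": 0.0},
    )


_PARAM_NAMES = ["alpha", "beta_age", "beta_male", "sigma_eta", "sigma_eps"]


def _observed_info_se(loglik_fn, theta_hat, names=_PARAM_NAMES) -> dict[str, float]:
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta_hat, loglik_fn)
    info = -H
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(theta_hat), np.nan)
    return dict(zip(names, se.tolist()))


# --------------------------------------------------------------------------
# predictions

def _record_fields(record) -> tuple[str, float, float, bool | None]:
    if isinstance(record, WaitRecord):
        return record.condition, record.age_months, record.male, record.censored
    if isinstance(record, Mapping) or isinstance(record, pd.Series):
        return (record["condition"], record["age_months"], record["male"],
                bool(record["censored"]) if "censored" in record else None)
    raise TypeError(f"unsupported record type {type(record)!r}")


def expected_ln_wait(fit: TobitREFit, record) -> float:
    """Expected log wait for a record's condition, age, and sex:
    fixed part plus the empirical-Bayes posterior mean of the
    condition's random effect (parameter estimates taken as truth)."""
    cond, age, male, _ = _record_fields(record)
    if cond not in fit.eb_eta.index:
        raise LookupError(f"condition {cond!r} not present in the fitted model")
    p = fit.params
    return float(p.alpha + p.beta_age * age + p.beta_male * male + fit.eb_eta[cond])


def impute_censored_ln_wait(
    fit: TobitREFit,
    record,
    n_draws: int = 10_000,
    seed: int | np.random.Generator | None = 0,
    integrate_eta: bool = False,
) -> float:
    """Monte-Carlo expected latent log wait for a censored record,
    conditional on the wait exceeding the censor limit and on the
    record's age, sex, and condition.

    Draws the individual error from Normal(0, sigma_eps^2) around the
    expected log wait, truncated below at log(censor).  By default the
    condition effect enters as its empirical-Bayes point estimate; with
    ``integrate_eta=True`` it is redrawn from a normal approximation to
    its posterior on every draw.
    """
    cond, age, male, cens = _record_fields(record)
    if cens is not None and not cens:
        raise ValueError("imputation is only defined for censored records")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = expected_ln_wait(fit, record)
    sig = fit.params.sigma_eps
    log_c = math.log(fit.params.censor_seconds)
    if integrate_eta:
        eta_draws = rng.normal(fit.eb_eta[cond], fit.eb_eta_sd[cond], size=n_draws)
        mu = mu - fit.eb_eta[cond] + eta_draws
    a = (log_c - mu) / sig
    draws = _truncated_normal_draws(mu, sig, a, n_draws, rng)
    return float(np.mean(draws))


def _truncated_normal_draws(mu, sigma, a, n_draws, rng):
    """Lower-truncated normal draws by inverse-CDF sampling, stable in
    the far tail (works through the log CDF complement)."""
    u = rng.uniform(size=n_draws)
    # quantile of the conditional law: Phi^-1(1 - u * SF(a))
    z = -ndtri(np.exp(np.log(u) + log_ndtr(-a)))
    return mu + sigma * z


# --------------------------------------------------------------------------
# RND

@dataclass
class RNDScores:
    """Per-participant deviation from the model-expected log wait, and
    its rank-normalized version (RND)."""

    deviation: pd.Series
    rnd: pd.Series


def compute_rnd(
    records: pd.DataFrame,
    fit: TobitREFit,
    seed: int | None = 0,
    n_draws: int = 10_000,
    integrate_eta: bool = False,
) -> RNDScores:
    """Deviation of each child's (possibly imputed) log wait from the
    model-expected log wait, rank-normalized within the sample.

    Censored records are replaced by the conditional expectation of the
    latent log wait (Monte Carlo, ``n_draws`` draws per record).
    """
    if not fit.converged:
        raise EstimationError("cannot compute RND from a non-converged fit")
    df = _prepare(records, fit.params.censor_seconds)
    p = fit.params
    eta = fit.eb_eta.reindex(df["condition"]).to_numpy()
    if np.isnan(eta).any():
        unknown = sorted(set(df["condition"]) - set(fit.eb_eta.index))
        raise LookupError(f"conditions not present in the fitted model: {unknown}")
    expected = p.fixed_part(df["age_months"], df["male"]) + eta
    ln_wait = np.log(df["wait_seconds"].to_numpy(float))
    cens = df["censored"].to_numpy(bool)
    if cens.any():
        rng = np.random.default_rng(seed)
        mu = expected[cens]
        if integrate_eta:
            eb_sd = fit.eb_eta_sd.reindex(df["condition"]).to_numpy()[cens]
            eta_draws = rng.normal(mu[None, :], eb_sd[None, :], size=(n_draws, mu.size))
            mu_mat = eta_draws  # already centered at mu
        else:
            mu_mat = np.broadcast_to(mu, (n_draws, mu.size))
        a = (math.log(p.censor_seconds) - mu_mat) / p.sigma_eps
        u = rng.uniform(size=(n_draws, mu.size))
        z = -ndtri(np.exp(np.log(u) + log_ndtr(-a)))
        ln_wait = ln_wait.copy()
        ln_wait[cens] = np.mean(mu_mat + p.sigma_eps * z, axis=0)
    deviation = pd.Series(ln_wait - expected, index=df["participant"].to_numpy(),
                          name="deviation")
    rnd = rank_inverse_normal(deviation).rename("rnd")
    return RNDScores(deviation=deviation, rnd=rnd)
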