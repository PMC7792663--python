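"""Censored random-effects wait-time model: likelihood correctness
(OLS and grid-integration oracles), empirical-Bayes shrinkage,
conditional imputation, and RND construction."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selfreg.synthetic import default_spec, generate_cohort
from selfreg.wait_model import (
    EstimationError,
    TobitParams,
    WaitRecord,
    compute_rnd,
    expected_ln_wait,
    fit_at_params,
    fit_tobit_re,
    impute_censored_ln_wait,
)


def _uncensored_records(seed=0, n=400, n_cond=8, sigma_eta=0.0):
    """Data with an effectively unreachable censor limit."""
    params = TobitParams(3.0, 0.05, -0.5, sigma_eta, 1.0, censor_seconds=1e9)
    spec = default_spec(
        seed=seed, n_participants=n, n_conditions=n_cond,
        condition_sizes=tuple([n // n_cond] * n_cond), tobit_params=params,
        survey_n=50,
    )
    return generate_cohort(spec).wait_records


class TestFitTobitRE:
    def test_no_censoring_no_re_equals_ols(self):
        """With nothing censored and sigma_eta fixed at zero the model is
        plain normal regression: estimates must match the closed form."""
        rec = _uncensored_records()
        fit = fit_tobit_re(rec, censor_seconds=1e9, fix_sigma_eta=0.0)
        X = np.column_stack([np.ones(len(rec)), rec["age_months"], rec["male"]])
        y = np.log(rec["wait_seconds"].to_numpy())
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sigma_ml = math.sqrt(resid @ resid / len(y))
        assert fit.params.alpha == pytest.approx(beta[0], abs=1e-4)
        assert fit.params.beta_age == pytest.approx(beta[1], abs=1e-6)
        assert fit.params.beta_male == pytest.approx(beta[2], abs=1e-5)
        assert fit.params.sigma_eps == pytest.approx(sigma_ml, abs=1e-4)

    def test_all_censored_has_no_interior_optimum(self):
        rec = _uncensored_records(n=60, n_cond=3)
        rec = rec.assign(wait_seconds=900.0, censored=True)
        with pytest.raises(EstimationError, match="no interior optimum"):
            fit_tobit_re(rec, censor_seconds=900.0)

    def test_single_condition_sigma_eta_unidentified(self):
        rec = _uncensored_records(n=50, n_cond=1)
        with pytest.raises(EstimationError, match="not identified"):
            fit_tobit_re(rec, censor_seconds=1e9)

    def test_censored_flag_must_sit_at_limit(self):
        rec = _uncensored_records(n=60, n_cond=3)
        rec.loc[0, "censored"] = True  # wait != limit
        with pytest.raises(ValueError, match="censored"):
            fit_tobit_re(rec, censor_seconds=1e9)

    def test_duplicate_participants_keep_first(self):
        rec = _uncensored_records(n=60, n_cond=3)
        dup = pd.concat([rec, rec.iloc[[0]].assign(wait_seconds=5.0)],
                        ignore_index=True)
        fit_a = fit_tobit_re(rec, censor_seconds=1e9, compute_se=False)
        fit_b = fit_tobit_re(dup, censor_seconds=1e9, compute_se=False)
        assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-6)

    def test_loglik_invariant_to_condition_relabeling(self, cohort):
        rec = cohort.wait_records
        fit = fit_at_params(rec, cohort.spec.tobit_params)
        relabeled = rec.assign(
            condition=rec["condition"].map(lambda c: f"z{c[::-1]}")
        )
        fit2 = fit_at_params(relabeled, cohort.spec.tobit_params)
        assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-8)

    def test_location_equivariance(self):
        """Scaling all waits by e^c (and the censor limit with them)
        shifts alpha by c and leaves slopes and SDs unchanged."""
        rec = generate_cohort(default_spec(seed=23)).wait_records
        c = 0.7
        scaled = rec.assign(wait_seconds=rec["wait_seconds"] * math.exp(c))
        fit = fit_tobit_re(rec, censor_seconds=900.0, compute_se=False)
        fit2 = fit_tobit_re(scaled, censor_seconds=900.0 * math.exp(c),
                            compute_se=False)
        assert fit2.params.alpha - fit.params.alpha == pytest.approx(c, abs=2e-3)
        assert fit2.params.beta_age == pytest.approx(fit.params.beta_age, abs=2e-4)
        assert fit2.params.beta_male == pytest.approx(fit.params.beta_male, abs=2e-3)
        assert fit2.params.sigma_eta == pytest.approx(fit.params.sigma_eta, abs=2e-3)
        assert fit2.params.sigma_eps == pytest.approx(fit.params.sigma_eps, abs=2e-3)

    def test_eb_eta_mean_near_zero(self, fitted):
        assert abs(fitted.eb_eta.mean()) < 0.05


class TestEmpiricalBayes:
    def test_matches_grid_integration(self, cohort):
        """Adaptive quadrature posterior means must agree with
        brute-force integration of the posterior on a fine grid."""
        fit = fit_at_params(cohort.wait_records, cohort.spec.tobit_params)
        p = cohort.spec.tobit_params
        rec = cohort.wait_records
        log_c = math.log(p.censor_seconds)
        eta_grid = np.linspace(-5 * p.sigma_eta, 5 * p.sigma_eta, 4001)
        for cond in list(fit.eb_eta.index)[:6]:
            sub = rec[rec["condition"] == cond]
            mu = p.fixed_part(sub["age_months"], sub["male"])
            logpost = stats.norm.logpdf(eta_grid, 0.0, p.sigma_eta)
            for (_, row), m in zip(sub.iterrows(), mu):
                if row["censored"]:
                    logpost += stats.norm.logsf(log_c, m + eta_grid, p.sigma_eps)
                else:
                    logpost += stats.norm.logpdf(
                        math.log(row["wait_seconds"]), m + eta_grid, p.sigma_eps
                    )
            w = np.exp(logpost - logpost.max())
            grid_mean = float((w * eta_grid).sum() / w.sum())
            assert fit.eb_eta[cond] == pytest.approx(grid_mean, abs=1e-4)

    def test_shrinkage_direction_single_extreme_child(self):
        """One condition holding a single large positive residual: its
        empirical-Bayes effect lies strictly between zero and the raw
        residual."""
        rec = _uncensored_records(n=90, n_cond=3, sigma_eta=0.5)
        extreme = pd.DataFrame(
            [{"participant": "x1", "condition": "solo", "age_months": 52.0,
              "male": 0, "wait_seconds": float(np.exp(8.0)), "censored": False}]
        )
        data = pd.concat([rec, extreme], ignore_index=True)
        params = TobitParams(3.0, 0.05, -0.5, 0.5, 1.0, censor_seconds=1e9)
        fit = fit_at_params(data, params)
        raw_resid = 8.0 - (3.0 + 0.05 * 52.0)
        assert 0.0 < fit.eb_eta["solo"] < raw_resid

    def test_eb_shrinks_harder_for_smaller_conditions(self):
        """Two conditions with the same mean residual: the smaller one
        is pulled closer to zero."""
        params = TobitParams(3.0, 0.0, 0.0, 0.5, 1.0, censor_seconds=1e9)
        rows = []
        for i in range(20):
            rows.append({"participant": f"b{i}", "condition": "big",
                         "age_months": 52.0, "male": 0,
                         "wait_seconds": float(np.exp(4.0)), "censored": False})
        for i in range(3):
            rows.append({"participant": f"s{i}", "condition": "small",
                         "age_months": 52.0, "male": 0,
                         "wait_seconds": float(np.exp(4.0)), "censored": False})
        fit = fit_at_params(pd.DataFrame(rows), params)
        assert 0 < fit.eb_eta["small"] < fit.eb_eta["big"] < 1.0

    def test_zero_sigma_eta_limit(self):
        rec = _uncensored_records(n=60, n_cond=3)
        params = TobitParams(3.0, 0.05, -0.5, 0.0, 1.0, censor_seconds=1e9)
        fit = fit_at_params(rec, params)
        assert (fit.eb_eta == 0).all()
        r = rec.iloc[0]
        expect = 3.0 + 0.05 * r["age_months"] - 0.5 * r["male"]
        assert expected_ln_wait(fit, r) == pytest.approx(expect)

    def test_unknown_condition_lookup_error(self, fitted):
        rec = WaitRecord("z", "no-such-condition", 52.0, 0, 900.0, True)
        with pytest.raises(LookupError):
            expected_ln_wait(fitted, rec)


class TestImputation:
    @pytest.mark.parametrize("mu,sigma", [(5.0, 1.0), (6.5, 2.5), (7.5, 0.5),
                                          (3.0, 2.0)])
    def test_matches_truncated_normal_closed_form(self, fitted, mu, sigma):
        """MC conditional mean vs mu + sigma*phi(a)/(1-Phi(a))."""
        import dataclasses

        fit = dataclasses.replace(
            fitted,
            params=TobitParams(mu, 0.0, 0.0, fitted.params.sigma_eta, sigma, 900.0),
            eb_eta=fitted.eb_eta.copy(),
        )
        cond = fit.eb_eta.index[0]
        fit.eb_eta[cond] = 0.0
        rec = WaitRecord("x", cond, 0.0, 0, 900.0, True)
        n_draws = 20_000
        est = impute_censored_ln_wait(fit, rec, n_draws=n_draws, seed=1)
        a = (math.log(900.0) - mu) / sigma
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        closed = mu + sigma * lam
        var = sigma**2 * (1 + a * lam - lam**2)
        assert abs(est - closed) < 3 * math.sqrt(var / n_draws)
        assert est > math.log(900.0)

    def test_nonbinding_truncation_returns_mu(self, fitted):
        import dataclasses

        fit = dataclasses.replace(
            fitted, params=TobitParams(20.0, 0.0, 0.0, 0.786, 0.5, 900.0),
            eb_eta=fitted.eb_eta.copy(),
        )
        cond = fit.eb_eta.index[0]
        fit.eb_eta[cond] = 0.0
        rec = WaitRecord("x", cond, 0.0, 0, 900.0, True)
        est = impute_censored_ln_wait(fit, rec, n_draws=5000, seed=2)
        assert est == pytest.approx(20.0, abs=0.05)

    def test_uncensored_record_rejected(self, fitted):
        cond = fitted.eb_eta.index[0]
        rec = WaitRecord("x", cond, 52.0, 0, 100.0, False)
        with pytest.raises(ValueError, match="censored"):
            impute_censored_ln_wait(fitted, rec)


class TestComputeRND:
    def test_seed_reproducible(self, cohort, fitted):
        a = compute_rnd(cohort.wait_records, fitted, seed=4)
        b = compute_rnd(cohort.wait_records, fitted, seed=4)
        pd.testing.assert_series_equal(a.rnd, b.rnd)

    def test_deviations_are_residuals_without_censoring(self):
        rec = _uncensored_records()
        fit = fit_tobit_re(rec, censor_seconds=1e9, fix_sigma_eta=0.0,
                           compute_se=False)
        rnd = compute_rnd(rec, fit, seed=0)
        X = np.column_stack([np.ones(len(rec)), rec["age_months"], rec["male"]])
        y = np.log(rec["wait_seconds"].to_numpy())
        p = fit.params
        resid = y - X @ np.array([p.alpha, p.beta_age, p.beta_male])
        np.testing.assert_allclose(
            rnd.deviation.to_numpy(), resid, atol=1e-10
        )
        # rank-normalized scores order exactly as the residuals
        assert (rnd.rnd.rank() == rnd.deviation.rank()).all()

    def test_rnd_mean_is_centered(self, cohort, fitted):
        rnd = compute_rnd(cohort.wait_records, fitted, seed=0)
        assert abs(rnd.rnd.mean()) < 1e-10  # rank-normal scores are symmetric
        assert abs(rnd.deviation.mean()) < 0.5

    def test_censored_participants_get_imputed_above_limit(self, cohort, fitted):
        rnd = compute_rnd(cohort.wait_records, fitted, seed=0)
        wr = cohort.wait_records.set_index("participant")
        cens = wr.index[wr["censored"]]
        p = fitted.params
        eta = fitted.eb_eta.reindex(wr.loc[cens, "condition"]).to_numpy()
        expected = p.fixed_part(wr.loc[cens, "age_months"],
                                wr.loc[cens, "male"]) + eta
        imputed_ln_wait = rnd.deviation.loc[cens].to_numpy() + expected
        assert (imputed_ln_wait > math.log(900.0)).all()
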