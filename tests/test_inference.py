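"""Inference battery: OLS against a normal-equations oracle, FDR
against brute-force step-up, permutation Wald behaviour, conjugate
shrinkage algebra, and coefficient averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from selfreg.inference import (
    AssocResult,
    InferenceError,
    PriorSpec,
    average_correlation,
    bayes_shrinkage,
    bh_fdr,
    mean_coefficient,
    ols_assoc,
    permutation_wald,
    power_check,
    run_battery,
    subgroup_analysis,
)


# --------------------------------------------------------------------------
# OLS

def _normal_equations_oracle(X, y):
    """Hand-rolled closed-form OLS with conventional SEs."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    se = np.sqrt(np.diag(xtx_inv) * (resid @ resid) / df)
    return beta, se, df


class TestOlsAssoc:
    def test_matches_normal_equations_on_small_fixture(self):
        rng = np.random.default_rng(42)
        n = 20
        pred = rng.normal(size=n)
        sex = rng.binomial(1, 0.5, size=n).astype(float)
        y = 0.4 * pred - 0.2 * sex + rng.normal(size=n)
        res = ols_assoc(pd.Series(y), pd.Series(pred), pd.Series(sex))
        X = np.column_stack([np.ones(n), pred, sex])
        beta, se, df = _normal_equations_oracle(X, y)
        assert res.coef == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)
        p = 2 * stats.t.sf(abs(beta[1] / se[1]), df)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.n == n

    def test_recovers_generative_slope(self):
        rng = np.random.default_rng(7)
        n = 5000
        pred = rng.normal(size=n)
        sex = rng.binomial(1, 0.5, size=n).astype(float)
        y = 0.3 * pred + rng.normal(size=n)
        res = ols_assoc(pd.Series(y), pd.Series(pred), pd.Series(sex))
        assert abs(res.coef - 0.3) < 3 * res.se
        null = ols_assoc(pd.Series(rng.normal(size=n)), pd.Series(pred), pd.Series(sex))
        assert abs(null.coef) < 3 * null.se

    def test_complete_case_alignment(self):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=30))
        y.iloc[:5] = np.nan
        pred = pd.Series(rng.normal(size=30))
        pred.iloc[5:8] = np.nan
        res = ols_assoc(y, pred, pd.Series(rng.binomial(1, 0.5, 30).astype(float)))
        assert res.n == 22

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        pred = pd.Series(rng.normal(size=30))
        with pytest.raises(InferenceError, match="collinear|rank"):
            ols_assoc(pd.Series(rng.normal(size=30)), pred, sex=2.0 * pred)

    def test_too_few_cases_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(InferenceError, match="complete cases"):
            ols_assoc(pd.Series(rng.normal(size=5)), pd.Series(rng.normal(size=5)),
                      pd.Series(np.ones(5)))


# --------------------------------------------------------------------------
# FDR

def _stepup_oracle(p, q):
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    ks = [i + 1 for i in range(m) if p[order[i]] <= (i + 1) * q / m]
    reject = np.zeros(m, dtype=bool)
    if ks:
        reject[order[: max(ks)]] = True
    return reject


class TestBhFdr:
    def test_worked_example(self):
        flags = bh_fdr([0.001, 0.02, 0.04, 0.2], q=0.1)
        np.testing.assert_array_equal(flags, [True, True, True, False])

    def test_all_ones_reject_none(self):
        assert not bh_fdr([1.0, 1.0, 1.0]).any()

    @pytest.mark.parametrize("bad", [[], [0.0, 0.5], [1.2], [np.nan]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    def test_agrees_with_brute_force_step_up(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            m = rng.integers(1, 20)
            p = rng.uniform(1e-6, 1.0, size=m)
            q = rng.uniform(0.01, 0.3)
            np.testing.assert_array_equal(bh_fdr(p, q), _stepup_oracle(p, q))


# --------------------------------------------------------------------------
# Bayesian shrinkage

class TestBayesShrinkage:
    def test_hand_computed_example(self):
        post = bayes_shrinkage((0.31, 0.10), PriorSpec(0.15, 0.2))
        # precision-weighted: (0.15/0.04 + 0.31/0.01) / (1/0.04 + 1/0.01)
        assert post.mean == pytest.approx(34.75 / 125, abs=1e-12)
        assert post.sd == pytest.approx(125 ** -0.5, abs=1e-12)

    def test_flat_prior_and_no_data_limits(self):
        assert bayes_shrinkage((0.3, 0.1), PriorSpec(0.0, 1e6)).mean == pytest.approx(0.3, abs=1e-6)
        assert bayes_shrinkage((0.3, 1e6), PriorSpec(0.15, 0.2)).mean == pytest.approx(0.15, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(-1, 1), st.floats(0.01, 2), st.floats(-1, 1), st.floats(0.01, 2))
    def test_convex_combination(self, coef, se, pm, psd):
        prior = PriorSpec(pm, psd)
        post = bayes_shrinkage((coef, se), prior)
        w = (1 / psd**2) / (1 / psd**2 + 1 / se**2)
        assert post.mean == pytest.approx(w * pm + (1 - w) * coef, abs=1e-9)
        assert post.sd < min(psd, se)
        lo, hi = sorted([pm, coef])
        assert lo - 1e-9 <= post.mean <= hi + 1e-9


# --------------------------------------------------------------------------
# permutation Wald

def _null_data(rng, n=113, m=11):
    outcomes = pd.DataFrame(rng.normal(size=(n, m)),
                            columns=[f"o{j}" for j in range(m)])
    pred = pd.Series(rng.normal(size=n))
    sex = pd.Series(rng.binomial(1, 0.5, n).astype(float))
    return outcomes, pred, sex


class TestPermutationWald:
    def test_exact_copy_outcome_gives_minimal_p(self, rng):
        outcomes, pred, sex = _null_data(rng)
        outcomes["o0"] = pred
        res = permutation_wald(outcomes, pred, sex, B=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_fixed_seed_reproducible(self, rng):
        outcomes, pred, sex = _null_data(rng)
        a = permutation_wald(outcomes, pred, sex, B=199, seed=5)
        b = permutation_wald(outcomes, pred, sex, B=199, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.perm_stats, b.perm_stats)

    def test_covariance_modes_agree_on_complete_data(self, rng):
        outcomes, pred, sex = _null_data(rng)
        a = permutation_wald(outcomes, pred, sex, B=99, seed=1, covariance="shared")
        b = permutation_wald(outcomes, pred, sex, B=99, seed=1,
                             covariance="complete_case")
        assert a.statistic == pytest.approx(b.statistic)

    def test_batched_and_loop_paths_agree(self, rng):
        """The vectorized complete-data path must equal the generic
        per-permutation loop (forced via a per-outcome missing value)."""
        outcomes, pred, sex = _null_data(rng, n=60, m=4)
        fast = permutation_wald(outcomes, pred, sex, B=99, seed=3)
        # per-outcome permutation disables batching; the observed
        # statistic is permutation-independent and must agree exactly
        loop = permutation_wald(outcomes, pred, sex, B=99, seed=3,
                                permute="per_outcome")
        assert loop.statistic == pytest.approx(fast.statistic, rel=1e-10)

    def test_small_B_rejected(self, rng):
        outcomes, pred, sex = _null_data(rng)
        with pytest.raises(ValueError):
            permutation_wald(outcomes, pred, sex, B=10)

    def test_empirical_p_bounds(self, rng):
        outcomes, pred, sex = _null_data(rng)
        res = permutation_wald(outcomes, pred, sex, B=99, seed=2)
        assert 1 / 100 <= res.p_value <= 1.0


# --------------------------------------------------------------------------
# averaging / subgroups

class TestAverages:
    def test_mean_coefficient_sign_handling(self):
        assocs = [AssocResult(f"o{i}", "p", c, 0.1, 0.5, 100)
                  for i, c in enumerate([0.2, -0.2, 0.4])]
        assert mean_coefficient(assocs) == pytest.approx(0.4 / 3)
        assert mean_coefficient(assocs, "positive") == pytest.approx(0.8 / 3)
        assert mean_coefficient(assocs, {"o1": -1}) == pytest.approx(0.8 / 3)

    def test_identical_outcomes_give_identical_coefficients(self, rng):
        n = 100
        pred = pd.Series(rng.normal(size=n))
        sex = pd.Series(rng.binomial(1, 0.5, n).astype(float))
        y = pd.Series(0.25 * pred + rng.normal(size=n))
        outcomes = pd.DataFrame({"a": y, "b": y, "c": y})
        avg = average_correlation(outcomes, pred, sex, bootstrap_B=200, seed=0)
        coefs = [a.coef for a in avg.assocs]
        assert np.ptp(coefs) == 0.0
        assert avg.mean == pytest.approx(coefs[0])
        assert avg.se <= max(a.se for a in avg.assocs)

    def test_independent_group_flag_centers_difference_at_zero(self, rng):
        n = 200
        pred = pd.Series(rng.normal(size=n))
        sex = pd.Series(rng.binomial(1, 0.5, n).astype(float))
        outcomes = pd.DataFrame({f"o{j}": 0.2 * pred + rng.normal(size=n)
                                 for j in range(5)})
        flag = pd.Series(rng.binomial(1, 0.5, n).astype(bool))
        res = subgroup_analysis(outcomes, pred, sex, flag, bootstrap_B=200, seed=0)
        d = res["difference"]
        assert abs(d["mean"]) < 3.5 * d["se"]

    def test_empty_subgroup_rejected(self, rng):
        n = 40
        pred = pd.Series(rng.normal(size=n))
        sex = pd.Series(np.ones(n))
        outcomes = pd.DataFrame({"o": rng.normal(size=n)})
        with pytest.raises(InferenceError):
            subgroup_analysis(outcomes, pred, sex,
                              pd.Series(np.zeros(n, dtype=bool)))


def test_power_increases_with_effect_size():
    """Monte-Carlo power of the FDR battery grows from null to
    prior-mean effects (reduced replicate counts for the check)."""
    import dataclasses

    from selfreg.synthetic import default_spec

    spec = dataclasses.replace(default_spec(), survey_n=113)
    null = power_check(spec, PriorSpec(0.0, 0.2), n_reps=12, B=99, seed=9,
                       target_mean_r=0.0)
    alt = power_check(spec, PriorSpec(0.15, 0.2), n_reps=12, B=99, seed=9)
    assert alt.fdr_power >= null.fdr_power
    assert alt.wald_power >= null.wald_power
    assert null.wald_power <= 0.25
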