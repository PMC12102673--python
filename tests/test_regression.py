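"""Count-regression core: VIF screen, IRLS fit, Wald/deviance/runs tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from pneumorisk import (
    GeneratorConfig,
    PoissonRiskModel,
    backward_eliminate_vif,
    chi2_critical,
    compute_vif,
    generate_covariates,
    predict_mean,
    rate_ratio,
    runs_test,
    simulate_counts,
    wald_critical,
)
from pneumorisk.datagen import calibrated_intercept
from pneumorisk.errors import (
    ConvergenceError,
    DegenerateInputError,
    InvalidArgumentError,
    RankDeficiencyError,
)


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        report = compute_vif(np.column_stack([x1, x2]), names=["a", "b"])
        assert report.vif["a"] == pytest.approx(1.0, abs=1e-12)
        assert report.vif["b"] == pytest.approx(1.0, abs=1e-12)
        assert report.tolerance["a"] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_predictor_is_infinite(self, rng):
        x = rng.normal(size=50)
        report = compute_vif(np.column_stack([x, x]), names=["a", "b"])
        assert np.isinf(report.vif["a"]) and np.isinf(report.vif["b"])

    def test_constructed_r2_gives_exact_vif(self, rng):
        # x2 = x1 + c*e with e orthogonal to {1, x1}, c set so R^2 = 0.9 exactly
        n = 200
        x1 = rng.normal(size=n)
        e = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), x1])
        e -= basis @ np.linalg.lstsq(basis, e, rcond=None)[0]
        x1c = x1 - x1.mean()
        c = math.sqrt((x1c @ x1c) / 9.0 / (e @ e))
        x2 = x1 + c * e
        report = compute_vif(np.column_stack([x1, x2]), names=["x1", "x2"])
        assert report.vif["x2"] == pytest.approx(10.0, abs=1e-6)
        # direct least-squares oracle
        beta, *_ = np.linalg.lstsq(basis, x2, rcond=None)
        resid = x2 - basis @ beta
        r2 = 1 - resid @ resid / np.sum((x2 - x2.mean()) ** 2)
        assert report.vif["x2"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-9)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = rng.normal(size=(80, 4))
        X[:, 3] += 0.8 * X[:, 0]
        report = compute_vif(X)
        design = np.column_stack([X, np.ones(len(X))])
        for j in range(4):
            assert report.vif.iloc[j] == pytest.approx(
                variance_inflation_factor(design, j), rel=1e-9
            )

    def test_rejects_degenerate_designs(self, rng):
        with pytest.raises(RankDeficiencyError):
            compute_vif(rng.normal(size=(3, 5)))
        X = rng.normal(size=(20, 2))
        X[:, 1] = 7.0
        with pytest.raises(InvalidArgumentError):
            compute_vif(X)
        with pytest.raises(InvalidArgumentError):
            compute_vif(rng.normal(size=(20, 1)))


class TestBackwardElimination:
    def test_collinear_triple_is_fully_removed(self):
        # temperature, humidity, health workers rebuilt as near-linear
        # combinations of survivors must be exactly the three eliminated
        cfg = GeneratorConfig(n_districts=500, seed=13, collinear_triple=True,
                              collinear_r2=0.95)
        table = generate_covariates(cfg)
        names = [s.name for s in cfg.covariates]
        reduced, report = backward_eliminate_vif(table[names], threshold=10.0)
        assert sorted(report.removed) == [
            "air_humidity", "air_temperature", "health_workers",
        ]
        assert set(reduced.columns) == set(names) - set(report.removed)
        assert (report.vif <= 10.0).all()

    def test_orthogonal_matrix_is_a_noop(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        reduced, report = backward_eliminate_vif(X, threshold=10.0)
        assert report.removed == []
        pd.testing.assert_frame_equal(reduced, X)

    def test_duplicate_column_tie_removes_later_column(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"first": x, "other": rng.normal(size=60), "second": x})
        reduced, report = backward_eliminate_vif(X, threshold=10.0)
        assert report.removed == ["second"]
        assert list(reduced.columns) == ["first", "other"]


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

class TestPoissonFit:
    def test_intercept_only_closed_form(self):
        # the intercept-only MLE is ln(mean(y)); mu = mean(y) for all rows
        res = PoissonRiskModel([1, 2, 3], np.empty((3, 0))).fit()
        assert res.params["intercept"] == pytest.approx(math.log(2.0), abs=1e-10)
        assert np.allclose(res.fittedvalues, 2.0, atol=1e-9)

    def test_two_group_closed_form(self):
        y = [2, 2, 2, 8, 8, 8]
        x = np.array([[0.0], [0.0], [0.0], [1.0], [1.0], [1.0]])
        res = PoissonRiskModel(y, x).fit()
        assert res.params["x0"] == pytest.approx(math.log(4.0), abs=1e-8)
        assert res.params["intercept"] == pytest.approx(math.log(2.0), abs=1e-8)

    def test_matches_statsmodels_glm(self, small_table):
        import statsmodels.api as sm

        predictors = [c for c in small_table.columns
                      if c not in ("district_id", "case_count")]
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        X = sm.add_constant(small_table[predictors].to_numpy())
        ref = sm.GLM(small_table["case_count"].to_numpy(), X,
                     family=sm.families.Poisson()).fit()
        assert np.allclose(res.params.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(res.bse.to_numpy(), ref.bse, rtol=1e-5)
        assert res.deviance == pytest.approx(ref.deviance, abs=1e-6)
        assert res.aic == pytest.approx(ref.aic, abs=1e-6)

    def test_score_equations_hold_at_convergence(self, small_table):
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        score = res.model.exog.T @ (res.model.endog - res.fittedvalues)
        assert np.max(np.abs(score)) < 1e-6

    def test_parameter_recovery_on_large_synthetic_table(self):
        cfg = GeneratorConfig(n_districts=2000, seed=41)
        table = generate_covariates(cfg)
        data = simulate_counts(table, cfg.coefficients, seed=42,
                               target_mean_count=cfg.target_mean_count)
        slopes = {k: v[0] for k, v in cfg.coefficients.items() if k != "intercept"}
        res = PoissonRiskModel.from_dataframe(
            data, predictors=list(slopes)
        ).fit()
        for name, truth in slopes.items():
            assert abs(res.params[name] - truth) < 3 * res.bse[name], name

    def test_covariate_rescaling_leaves_z_invariant(self, small_table):
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        scaled = small_table.copy()
        scaled["rainfall"] = scaled["rainfall"] * 100.0
        res2 = PoissonRiskModel.from_dataframe(scaled).fit()
        assert res2.params["rainfall"] == pytest.approx(
            res.params["rainfall"] / 100.0, rel=1e-6
        )
        z1 = res.params["rainfall"] / res.bse["rainfall"]
        z2 = res2.params["rainfall"] / res2.bse["rainfall"]
        assert z2 == pytest.approx(z1, abs=1e-8)

    def test_invalid_counts_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(InvalidArgumentError):
            PoissonRiskModel([1, -1] + [0] * 8, X)
        with pytest.raises(InvalidArgumentError):
            PoissonRiskModel([0.5] * 10, X)

    def test_nonconvergence_carries_last_iterate(self, small_table):
        model = PoissonRiskModel.from_dataframe(small_table)
        with pytest.raises(ConvergenceError) as err:
            model.fit(tol=1e-14, max_iter=2)
        assert err.value.last_result is not None
        assert not err.value.last_result.converged

    def test_deviance_nonincreasing_over_iterations(self, small_table):
        # step-halving IRLS: deviance at successive max_iter caps never rises
        model = PoissonRiskModel.from_dataframe(small_table)
        devs = []
        for cap in range(1, 8):
            try:
                devs.append(model.fit(max_iter=cap).deviance)
            except ConvergenceError as err:
                devs.append(err.last_result.deviance)
        assert all(d2 <= d1 + 1e-10 for d1, d2 in zip(devs, devs[1:]))


# ---------------------------------------------------------------------------
# tests on the fit
# ---------------------------------------------------------------------------

class TestWald:
    def test_published_malnutrition_coefficient_is_significant(self):
        z = 1.786 / 0.4834
        assert z == pytest.approx(3.695, abs=5e-4)
        assert abs(z) > wald_critical(0.1)

    def test_zero_estimate_is_never_significant(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        res = PoissonRiskModel([3, 3, 3, 3], x).fit()
        wt = res.wald_tests(alpha=0.1)
        assert wt.loc["x0", "z_score"] == pytest.approx(0.0, abs=1e-6)
        assert not wt.loc["x0", "significant"]

    def test_critical_value_brackets_published_rounding(self):
        c = wald_critical(0.1)
        assert 1.64 <= round(c, 2) <= 1.65
        assert round(c, 3) == 1.645

    def test_significance_flag_matches_definition(self, small_table):
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        wt = res.wald_tests(alpha=0.1)
        assert (wt["significant"] == (wt["z_score"].abs() > wt["critical"])).all()


class TestDevianceTest:
    def test_published_worked_example(self, small_table):
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        dt = res.deviance_test(df=10, alpha=0.1)
        assert dt.critical == pytest.approx(15.987, abs=5e-4)
        # the published fit: deviance 118.56 exceeds the critical value
        assert 118.56 > dt.critical

    def test_zero_deviance_never_rejects(self):
        y = [2, 2, 2, 8, 8, 8]
        x = np.array([[0.0]] * 3 + [[1.0]] * 3)
        res = PoissonRiskModel(y, x).fit()  # saturated two-group model
        dt = res.deviance_test(alpha=0.1)
        assert dt.statistic == pytest.approx(0.0, abs=1e-8)
        assert not dt.reject

    def test_critical_against_quadrature_oracle(self):
        # chi-square density integrated numerically, independent of the ppf
        df = 10

        def pdf(x):
            return x ** (df / 2 - 1) * math.exp(-x / 2) / (
                2 ** (df / 2) * math.gamma(df / 2)
            )

        crit = chi2_critical(0.1, df)
        mass, _ = quad(pdf, 0, crit)
        assert mass == pytest.approx(0.9, abs=1e-8)

    def test_df_validation(self, small_table):
        res = PoissonRiskModel.from_dataframe(small_table).fit()
        with pytest.raises(InvalidArgumentError):
            res.deviance_test(df=0)


class TestRunsTest:
    def test_alternating_signs_formula(self):
        r = runs_test([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        assert r.runs == 6
        assert r.expected == pytest.approx(4.0)

    def test_normal_approximation_close_to_exact_enumeration(self):
        # all 70 arrangements of 4 plus / 4 minus signs
        n_pos = n_neg = 4
        runs_of = []
        for positions in itertools.combinations(range(8), n_pos):
            signs = np.full(8, -1.0)
            signs[list(positions)] = 1.0
            runs_of.append(1 + int(np.sum(signs[1:] != signs[:-1])))
        runs_of = np.array(runs_of)
        expected = 2 * n_pos * n_neg / 8 + 1
        for r_obs in np.unique(runs_of):
            exact_p = np.mean(np.abs(runs_of - expected) >= abs(r_obs - expected))
            signs = _sign_sequence_with_runs(r_obs, n_pos, n_neg)
            approx_p = runs_test(signs).p_value
            assert abs(approx_p - exact_p) < 0.1, r_obs

    def test_balanced_sequence_has_large_p(self):
        # R == E[R] (5 runs for n+=n-=4) -> continuity-corrected z ~ 0
        r = runs_test([1, 1, -1, -1, 1, 1, -1, -1])
        assert r.runs == 4
        r5 = runs_test(_sign_sequence_with_runs(5, 4, 4))
        assert r5.runs == 5 and r5.p_value >= 0.5

    def test_zeros_dropped_and_one_sign_rejected(self):
        with pytest.raises(DegenerateInputError):
            runs_test([1.0, 2.0, 0.0, 3.0])
        with pytest.raises(InvalidArgumentError):
            runs_test([1.0])


def _sign_sequence_with_runs(r, n_pos, n_neg):
    """A +/-1 sequence with exactly r runs, n_pos plus and n_neg minus."""
    n_blocks_pos = math.ceil(r / 2)
    n_blocks_neg = r // 2
    seq = []
    pos_left, neg_left = n_pos, n_neg
    for i in range(r):
        if i % 2 == 0:
            blocks_after = n_blocks_pos - (i // 2) - 1
            take = pos_left - blocks_after
            seq += [1.0] * take
            pos_left -= take
        else:
            blocks_after = n_blocks_neg - (i // 2) - 1
            take = neg_left - blocks_after
            seq += [-1.0] * take
            neg_left -= take
    return seq


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

class TestPrediction:
    def test_malnutrition_rate_ratio_rounds_to_six(self):
        rr = rate_ratio(1.786)
        assert rr == pytest.approx(5.966, abs=5e-3)
        assert round(rr) == 6

    def test_all_zero_vector_returns_exp_intercept(self):
        coefs = {"intercept": (1.5, 0.1), "a": (0.3, 0.1)}
        assert predict_mean(coefs, {"a": 0.0}) == pytest.approx(math.exp(1.5))

    def test_protective_coefficient_has_rate_ratio_below_one(self):
        assert rate_ratio(-0.021) < 1.0

    def test_missing_covariate_rejected(self):
        coefs = {"intercept": (1.0, 0.1), "a": (0.3, 0.1)}
        with pytest.raises(InvalidArgumentError):
            predict_mean(coefs, {"b": 1.0})
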