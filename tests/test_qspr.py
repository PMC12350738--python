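"""The packaged drug table and the regression study around it."""

import numpy as np
import pandas as pd
import pytest

from mpolykit import (cv_metrics, equation_report, external_metrics, fit_model,
                      load_fixture, pearson_matrix)
from mpolykit.qspr import (DEFAULT_PREDICTORS, INDEX_COLUMNS, PROPERTY_COLUMNS,
                           FixtureIntegrityError, UnsupportedForNonlinear)


@pytest.fixture(scope="module")
def table():
    return load_fixture()


def synthetic_linear(n=45, noise=0.0, seed=0, a=3.0, b=2.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 10, n)
    y = a + b * x + rng.normal(0, noise, n)
    return pd.DataFrame({"mM2": x, "y": y})


class TestFixture:
    def test_shape_and_completeness(self, table):
        assert len(table) == 45
        assert not table.isna().any().any()
        assert set(INDEX_COLUMNS) <= set(table.columns)
        assert set(PROPERTY_COLUMNS) <= set(table.columns)

    @pytest.mark.parametrize("name,column,expected", [
        ("Acetaminophen", "M1", 50), ("Acetaminophen", "F", 124),
        ("Acetaminophen", "MW", 151.16), ("Metformin", "MW", 129.16),
        ("Ibuprofen", "M2", 77), ("Gabapentin", "ReZG3", 316),
        ("Xanax", "pubchem_cid", 2118),
    ])
    def test_spot_cells(self, table, name, column, expected):
        row = table.set_index("name").loc[name]
        assert row[column] == pytest.approx(expected)

    def test_index_columns_match_recomputation_from_fixture_graphs(
            self, table, drug_graphs):
        # for the four hand-encoded structures, every computable index cell
        # of the packaged table equals a fresh graph-route computation
        from mpolykit import all_indices
        by_name = table.set_index("name")
        title = {"acetaminophen": "Acetaminophen", "metformin": "Metformin",
                 "ibuprofen": "Ibuprofen", "gabapentin": "Gabapentin"}
        for key, g in drug_graphs.items():
            row = by_name.loc[title[key]]
            for r in all_indices(g):
                if r.route != "kernel" or r.name == "Ralpha":
                    continue
                # printed cells carry 4 decimals -> rounding error up to 5e-5
                assert row[r.name] == pytest.approx(r.as_float(), abs=6e-5), (key, r.name)

    def test_checksum_guard(self, monkeypatch):
        import mpolykit.qspr as q
        monkeypatch.setattr(q, "_FIXTURE_SHA256", "0" * 64)
        with pytest.raises(FixtureIntegrityError):
            q.load_fixture()


class TestFitModel:
    def test_exact_linear_data_recovered(self):
        t = synthetic_linear()
        rep = fit_model(t, "y", ("mM2",), "ols")
        assert rep.intercept == pytest.approx(3.0, abs=1e-9)
        assert rep.coefficients["mM2"] == pytest.approx(2.0, abs=1e-9)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)

    def test_in_sample_ols_r2_equals_squared_correlation(self):
        t = synthetic_linear(noise=2.0, seed=5)
        rep = fit_model(t, "y", ("mM2",), "ols")
        assert rep.r2 == pytest.approx(rep.r2_corr, abs=1e-10)

    def test_fixture_mw_model_is_strong_with_positive_coefficients(self, table):
        rep = fit_model(table, "MW", DEFAULT_PREDICTORS, "ols")
        assert rep.r2 > 0.9
        assert rep.coefficients["mM2"] > 0 and rep.coefficients["ReZG3"] > 0

    def test_zero_penalty_ridge_matches_ols(self, table):
        ols = fit_model(table, "MW", DEFAULT_PREDICTORS, "ols")
        ridge = fit_model(table, "MW", DEFAULT_PREDICTORS, "ridge",
                          hyperparams={"alpha": 0.0})
        for name in DEFAULT_PREDICTORS:
            assert ridge.coefficients[name] == pytest.approx(
                ols.coefficients[name], abs=1e-6)
        assert ridge.intercept == pytest.approx(ols.intercept, abs=1e-6)

    @pytest.mark.parametrize("kind", ["lasso", "elasticnet"])
    def test_vanishing_penalty_regularizers_approach_ols(self, table, kind):
        ols = fit_model(table, "MW", DEFAULT_PREDICTORS, "ols")
        reg = fit_model(table, "MW", DEFAULT_PREDICTORS, kind,
                        hyperparams={"alpha": 1e-10})
        for name in DEFAULT_PREDICTORS:
            assert reg.coefficients[name] == pytest.approx(
                ols.coefficients[name], rel=1e-4, abs=1e-4)

    def test_constant_target_rejected(self):
        t = synthetic_linear()
        t["y"] = 7.0
        with pytest.raises(ValueError, match="constant target"):
            fit_model(t, "y", ("mM2",), "ols")

    def test_unknown_column_names_valid_ones(self, table):
        with pytest.raises(KeyError, match="valid columns"):
            fit_model(table, "nope", DEFAULT_PREDICTORS)


class TestCrossValidation:
    def test_exact_linear_any_k(self):
        t = synthetic_linear()
        for k in (2, 5, 9):
            rep = cv_metrics(t, "y", ("mM2",), "ols", k=k)
            assert rep.r2 == pytest.approx(1.0, abs=1e-10)
            assert rep.rmse == pytest.approx(0.0, abs=1e-8)

    def test_fixture_mw_strongly_predicted(self, table):
        rep = cv_metrics(table, "MW", DEFAULT_PREDICTORS, "ols", k=5, seed=0)
        assert rep.r > 0.9

    def test_permutation_destroys_predictive_skill(self, table):
        # under a shuffled target, pooled out-of-fold predictions carry no
        # skill: R2_cv collapses in >= 9/10 seeds and the p-value of the
        # observed-vs-predicted correlation is not systematically small
        hits = 0
        ps = []
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            tt = table.copy()
            tt["MW"] = rng.permutation(tt["MW"].to_numpy())
            rep = cv_metrics(tt, "MW", DEFAULT_PREDICTORS, "ols", k=5, seed=s)
            hits += rep.r2 < 0.2
            ps.append(rep.p_value)
        assert hits >= 9

    def test_permutation_null_median_p_large(self, table):
        ps = []
        for s in range(50):
            rng = np.random.default_rng(12345 + s)
            tt = table.copy()
            tt["MW"] = rng.permutation(tt["MW"].to_numpy())
            ps.append(cv_metrics(tt, "MW", DEFAULT_PREDICTORS, "ols",
                                 k=5, seed=s).p_value)
        assert np.median(ps) > 0.3

    def test_bad_fold_count_rejected(self, table):
        with pytest.raises(ValueError):
            cv_metrics(table, "MW", DEFAULT_PREDICTORS, k=1)
        with pytest.raises(ValueError):
            cv_metrics(table, "MW", DEFAULT_PREDICTORS, k=46)


class TestExternalValidation:
    def test_exact_linear_perfect_holdout(self):
        t = synthetic_linear()
        rep = external_metrics(t, "y", ("mM2",), "ols", seed=0)
        assert rep.r2 == pytest.approx(1.0, abs=1e-10)

    def test_determinism_for_equal_seeds(self, table):
        a = external_metrics(table, "MW", DEFAULT_PREDICTORS, "ridge", seed=7)
        b = external_metrics(table, "MW", DEFAULT_PREDICTORS, "ridge", seed=7)
        assert a == b

    def test_resampled_median_holdout_r2_high(self, table):
        r2s = [external_metrics(table, "MW", DEFAULT_PREDICTORS, "ols",
                                test_fraction=0.2, seed=s).r2
               for s in range(20)]
        assert np.median(r2s) > 0.85

    def test_parameter_recovery_within_three_standard_errors(self, table):
        # y = a + b*mM2 + c*ReZG3 + noise at signal-to-noise ~ 10, n = 45
        X = table[["mM2", "ReZG3"]].to_numpy(float)
        a, b, c = 10.0, 5.0, 0.3
        signal = a + b * X[:, 0] + c * X[:, 1]
        sigma = signal.std() / 10
        design = np.column_stack([np.ones(len(X)), X])
        cov_unscaled = np.linalg.inv(design.T @ design)
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            y = signal + rng.normal(0, sigma, len(signal))
            t = pd.DataFrame({"mM2": X[:, 0], "ReZG3": X[:, 1], "y": y})
            rep = fit_model(t, "y", ("mM2", "ReZG3"), "ols")
            beta = np.array([rep.intercept, rep.coefficients["mM2"],
                             rep.coefficients["ReZG3"]])
            resid = y - design @ beta
            s2 = resid @ resid / (len(y) - 3)
            se = np.sqrt(np.diag(s2 * cov_unscaled))
            hits += all(abs(beta - np.array([a, b, c])) <= 3 * se)
        assert hits / n_rep >= 0.95


class TestPearsonMatrix:
    def test_self_correlation_is_one_with_three_stars(self, table):
        corr = pearson_matrix(table, index_cols=("M1",), property_cols=("M1",))
        assert corr.r.loc["M1", "M1"] == pytest.approx(1.0)
        assert corr.stars.loc["M1", "M1"] == "***"

    def test_m1_vs_mw_strong_and_significant(self, table):
        corr = pearson_matrix(table)
        assert corr.r.loc["M1", "MW"] >= 0.9
        assert corr.p.loc["M1", "MW"] < 0.001

    def test_anticorrelation_kept_signed_but_clipped_for_display(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 3, 2, 1]})
        corr = pearson_matrix(t, index_cols=("a",), property_cols=("b",))
        assert corr.r.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.clipped().loc["a", "b"] == 0.0

    def test_zero_variance_column_flagged_not_fatal(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        corr = pearson_matrix(t, index_cols=("a",), property_cols=("b",))
        assert np.isnan(corr.r.loc["a", "b"])
        assert corr.stars.loc["a", "b"] == "var=0"


class TestEquationReport:
    def test_simple_rendering(self):
        t = synthetic_linear()
        rep = fit_model(t, "y", ("mM2",), "ols")
        assert equation_report(rep) == "y = 3.0000 + (2.0000)*mM2"

    def test_zero_coefficient_retained(self):
        t = synthetic_linear()
        t["ReZG3"] = 1.0  # zero-variance predictor gets coefficient 0
        t["ReZG3"] += np.arange(len(t)) * 0  # keep dtype float
        t.loc[0, "ReZG3"] = 1.0000001  # avoid scaler blowup, ~zero slope
        rep = fit_model(t, "y", ("mM2", "ReZG3"), "lasso",
                        hyperparams={"alpha": 1.0})
        text = equation_report(rep)
        assert "(0.0000)*ReZG3" in text or "(-0.0000)*ReZG3" in text

    def test_svr_rejected(self, table):
        rep = cv_metrics(table, "MW", DEFAULT_PREDICTORS, "svr")
        with pytest.raises(UnsupportedForNonlinear):
            equation_report(rep)

    def test_fixture_mw_equation_signs(self, table):
        rep = fit_model(table, "MW", DEFAULT_PREDICTORS, "ols")
        text = equation_report(rep)
        assert text.startswith("MW = ")
        assert "(-" not in text
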