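"""Heteroscedastic model fitting, AIC ranking, Akaike weights, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from frugnet.model import (
    ModelSpec,
    akaike_weights,
    default_model_set,
    design_matrix,
    fit_gls_fixed_variance,
    per_species_linear_fit,
    predict_interaction_matrix,
    rank_models,
    variable_importance,
)
from frugnet.synth import GENERATING_SPEC, CommunityConfig, generate_community, _truth_design
from frugnet.predictors import build_predictor_table


def simple_table(y, v=None, size=None):
    """Minimal predictor table with controllable response and variance column."""
    n = len(y)
    birds = ["b1", "b2"] * (n // 2) + ["b1"] * (n % 2)
    grid = np.arange(n, dtype=float)
    table = pd.DataFrame(
        {
            "plant": [f"p{i}" for i in range(n)],
            "bird": birds,
            "response": y,
            "size_overlap": size if size is not None else (v if v is not None else np.ones(n)),
            "temporal_overlap": 100.0 * (grid + 1) / (n + 1),
            "abundance_product": 0.1 + (grid % 3) + 0.05 * grid**2,
            "fibre": 5.0 + np.sin(grid) * 3.0 + grid * 0.3,
            "proteins": 2.0 + (grid % 4),
            "sugars": 40.0 + np.cos(grid) * 20.0,
            "lipids": 1.0 + np.sqrt(grid),
            "bird_identity": pd.Categorical(birds),
        }
    )
    return table


def gaussian_tables(n_tables, seed=0):
    """Synthetic predictor tables drawn from the generating model itself."""
    dataset, truth = generate_community(CommunityConfig(seed=1))
    table = build_predictor_table(dataset, web=None)
    mean = _truth_design(table, truth)
    v = table["size_overlap"].to_numpy()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_tables):
        t = table.copy()
        t["response"] = mean + rng.normal(0.0, np.sqrt(truth.config.sigma2 * v))
        out.append(t)
    return out, truth, v


class TestFitGLS:
    def test_intercept_only_closed_form(self):
        table = simple_table([1.0, 2.0, 3.0])
        fit = fit_gls_fixed_variance(table, ModelSpec("null", ()))
        assert fit.coefficients.iloc[0] == pytest.approx(2.0)
        assert fit.sigma2 == pytest.approx(2.0 / 3.0)
        assert fit.aic == pytest.approx(11.297, abs=5e-4)
        assert fit.n_parameters == 2

    def test_aic_identity(self):
        table = simple_table(np.linspace(0, 3, 12), v=np.linspace(1, 5, 12))
        for spec in [ModelSpec("null", ()), ModelSpec("m", ("temporal_overlap",))]:
            fit = fit_gls_fixed_variance(table, spec)
            assert fit.aic == pytest.approx(
                -2 * fit.log_likelihood + 2 * fit.n_parameters
            )

    def test_beta_invariant_to_variance_scale(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=10)
        t1 = simple_table(y, v=np.ones(10))
        t2 = simple_table(y, v=np.full(10, 7.5))
        spec = ModelSpec("m", ("temporal_overlap", "abundance_product"))
        f1 = fit_gls_fixed_variance(t1, spec)
        f2 = fit_gls_fixed_variance(t2, spec)
        np.testing.assert_allclose(
            f1.coefficients.to_numpy(), f2.coefficients.to_numpy(), rtol=1e-10
        )
        assert f2.sigma2 == pytest.approx(f1.sigma2 / 7.5)

    def test_unit_variance_equals_ols(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=14)
        table = simple_table(y, v=np.ones(14))
        spec = ModelSpec("m", ("temporal_overlap", "fibre"))
        fit = fit_gls_fixed_variance(table, spec)
        X = design_matrix(table, spec).to_numpy()
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_ols, atol=1e-8)

    def test_nonpositive_variance_rejected(self):
        table = simple_table([1.0, 2.0, 3.0], v=np.array([1.0, 0.0, 2.0]))
        with pytest.raises(ValueError, match="strictly positive"):
            fit_gls_fixed_variance(table, ModelSpec("null", ()))

    def test_rank_deficiency_names_columns(self):
        table = simple_table(np.arange(8.0))
        table["sugars"] = table["temporal_overlap"] * 2.0
        with pytest.raises(np.linalg.LinAlgError, match="sugars"):
            fit_gls_fixed_variance(
                table, ModelSpec("m", ("temporal_overlap", "sugars"))
            )

    def test_matches_independent_numeric_likelihood_maximization(self):
        """WLS solution equals a direct numeric maximization of the Gaussian
        likelihood in (beta, log sigma2), on data drawn from the model."""
        from oracles import numeric_ml_fit

        tables, truth, v = gaussian_tables(3, seed=11)
        spec = GENERATING_SPEC
        for table in tables:
            fit = fit_gls_fixed_variance(table, spec)
            X = design_matrix(table, spec).to_numpy()
            y = table["response"].to_numpy()
            beta_hat, loglik = numeric_ml_fit(X, y, v)
            np.testing.assert_allclose(
                beta_hat, fit.coefficients.to_numpy(), atol=1e-6
            )
            assert loglik == pytest.approx(fit.log_likelihood, abs=1e-6)

    def test_ml_solution_is_local_optimum(self):
        tables, truth, v = gaussian_tables(1, seed=3)
        table = tables[0]
        spec = ModelSpec("m", ("size_overlap", "temporal_overlap"))
        fit = fit_gls_fixed_variance(table, spec)
        X = design_matrix(table, spec).to_numpy()
        y = table["response"].to_numpy()

        def loglik(beta, s2):
            resid = y - X @ beta
            return -0.5 * (
                len(y) * np.log(2 * np.pi * s2)
                + np.sum(np.log(v))
                + np.sum(resid**2 / (s2 * v))
            )

        best = loglik(fit.coefficients.to_numpy(), fit.sigma2)
        rng = np.random.default_rng(7)
        for _ in range(100):
            beta = fit.coefficients.to_numpy() + rng.normal(0, 0.05, X.shape[1])
            s2 = fit.sigma2 * np.exp(rng.normal(0, 0.2))
            assert loglik(beta, s2) <= best + 1e-9


class TestRanking:
    def test_equal_aic_gives_equal_weights(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_delta_two_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_single_model_weight_one(self):
        np.testing.assert_allclose(akaike_weights([3.2]), [1.0])

    def test_weights_shift_invariant(self):
        aics = np.array([12.0, 15.5, 13.1])
        np.testing.assert_allclose(
            akaike_weights(aics), akaike_weights(aics + 1000.0), rtol=1e-12
        )

    def test_rank_models_sorted_and_normalized(self):
        tables, _, _ = gaussian_tables(1, seed=9)
        specs = [ModelSpec("null", ()), GENERATING_SPEC, ModelSpec("size", ("size_overlap",))]
        ms = rank_models(tables[0], specs)
        aics = [f.aic for f in ms.fits]
        assert aics == sorted(aics)
        assert ms.akaike_weights.sum() == pytest.approx(1.0)
        assert ms.best.spec.name == GENERATING_SPEC.name

    def test_failed_fit_names_model(self):
        table = simple_table(np.arange(8.0))
        table["sugars"] = table["temporal_overlap"]
        with pytest.raises(RuntimeError, match="'collinear'|collinear|sugars"):
            rank_models(
                table,
                [ModelSpec("bad", ("temporal_overlap", "sugars"))],
            )


class TestImportance:
    @staticmethod
    def _fake_model_set(weights, specs):
        from frugnet.model import FitResult, ModelSet

        fits = [
            FitResult(
                spec=s,
                coefficients=pd.Series([0.0]),
                sigma2=1.0,
                log_likelihood=0.0,
                aic=float(i),
                n_parameters=1,
                fitted=np.zeros(1),
            )
            for i, s in enumerate(specs)
        ]
        return ModelSet(fits=fits, akaike_weights=np.asarray(weights))

    def test_hand_arithmetic(self):
        specs = [
            ModelSpec("m1", ("fibre",)),
            ModelSpec("m2", ("fibre", "sugars")),
            ModelSpec("m3", ("sugars",)),
        ]
        ms = self._fake_model_set([0.5, 0.3, 0.2], specs)
        imp = variable_importance(ms).set_index("variable")
        assert imp.loc["fibre", "averaged_weight"] == pytest.approx(0.4)
        assert imp.loc["fibre", "n_models"] == 2

    def test_variable_in_every_model(self):
        specs = [ModelSpec(f"m{i}", ("fibre",)) for i in range(4)]
        ms = self._fake_model_set([0.4, 0.3, 0.2, 0.1], specs)
        imp = variable_importance(ms).set_index("variable")
        assert imp.loc["fibre", "averaged_weight"] == pytest.approx(0.25)

    def test_interaction_terms_count_parents(self):
        specs = [
            ModelSpec("m1", ("fibre", "bird_identity", "fibre:bird_identity")),
            ModelSpec("m2", ("sugars",)),
        ]
        ms = self._fake_model_set([0.7, 0.3], specs)
        imp = variable_importance(ms).set_index("variable")
        assert imp.loc["bird_identity", "summed_weight"] == pytest.approx(0.7)
        assert imp.loc["bird_identity", "n_models"] == 1


class TestDefaultModelSet:
    def test_twenty_four_models_with_null(self):
        specs = default_model_set()
        assert len(specs) == 24
        assert any(len(s.terms) == 0 for s in specs)
        assert len({s.name for s in specs}) == 24

    def test_membership_counts(self):
        specs = default_model_set()
        counts = {}
        for spec in specs:
            for var in spec.variables:
                counts[var] = counts.get(var, 0) + 1
        assert counts == {
            "size_overlap": 3,
            "temporal_overlap": 7,
            "abundance_product": 7,
            "bird_identity": 14,
            "fibre": 5,
            "proteins": 5,
            "sugars": 5,
            "lipids": 5,
        }

    def test_term_cap(self):
        assert all(len(s.terms) <= 5 for s in default_model_set())


class TestPrediction:
    def test_back_transform_inverts_forward(self, toy_dataset):
        from frugnet.community import build_interaction_matrix

        web = build_interaction_matrix(toy_dataset)
        table = build_predictor_table(toy_dataset, web)
        fit = fit_gls_fixed_variance(table, ModelSpec("null", ()))
        fit.fitted = np.full(len(table), np.log(21.0))
        predicted = predict_interaction_matrix(fit, table, log_offset=1.0)
        np.testing.assert_allclose(predicted.matrix, 20.0)

    def test_zero_prediction(self, toy_dataset):
        from frugnet.community import build_interaction_matrix

        web = build_interaction_matrix(toy_dataset)
        table = build_predictor_table(toy_dataset, web)
        fit = fit_gls_fixed_variance(table, ModelSpec("null", ()))
        fit.fitted = np.zeros(len(table))
        predicted = predict_interaction_matrix(fit, table, log_offset=1.0)
        np.testing.assert_allclose(predicted.matrix, 0.0)

    def test_predicted_correlates_with_generating_frequencies(self):
        from scipy.stats import spearmanr
        from frugnet.community import build_interaction_matrix
        from frugnet.synth import generate_dataset

        dataset, truth = generate_dataset(CommunityConfig(seed=4))
        web = build_interaction_matrix(dataset)
        table = build_predictor_table(dataset, web)
        fit = fit_gls_fixed_variance(table, GENERATING_SPEC)
        predicted = predict_interaction_matrix(fit, table)
        rho = spearmanr(
            predicted.matrix.ravel(), truth.expected_frequency
        ).statistic
        assert rho > 0.5


class TestPerSpeciesFit:
    def test_collinear_rows_r2_one(self):
        table = simple_table(np.zeros(8))
        sub = table["bird"] == "b1"
        table.loc[sub, "response"] = 2.0 * table.loc[sub, "sugars"] + 1.0
        slope, intercept, r2 = per_species_linear_fit(table, "sugars", "b1")
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        table = simple_table(np.ones(8))
        _, _, r2 = per_species_linear_fit(table, "sugars", "b1")
        assert r2 == pytest.approx(0.0)

    def test_five_point_textbook_ols(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 3.9, 4.1, 5.5])
        table = simple_table(np.zeros(10))
        table.loc[table["bird"] == "b1", "sugars"] = x
        table.loc[table["bird"] == "b1", "response"] = y
        slope, intercept, r2 = per_species_linear_fit(table, "sugars", "b1")
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert slope == pytest.approx(sxy / sxx)
        assert intercept == pytest.approx(y.mean() - sxy / sxx * x.mean())
        assert r2 == pytest.approx(sxy**2 / (sxx * ((y - y.mean()) ** 2).sum()))

    def test_too_few_rows_error(self):
        table = simple_table(np.zeros(3))
        with pytest.raises(ValueError, match="3 rows|rows"):
            per_species_linear_fit(table, "sugars", "b2")
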