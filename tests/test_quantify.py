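import numpy as np
import pandas as pd
import pytest

from odormon import simulate
from odormon.datamodel import (
    AIR,
    FRESH_WASTE,
    LANDFILL_CLASSES,
    LANDFILL_GAS,
    LEACHATE,
    TrainingSet,
    ValidationError,
)
from odormon.features import build_training_set, extract_features
from odormon.classify import KnnClassifier
from odormon.quantify import (
    DoubleStepModel,
    estimate_ldl,
    fit_double_step,
    fit_global,
    fit_pls,
    predict_concentration,
    residual_diagnostics,
    select_components,
)


def _centered(X):
    X = pd.DataFrame(X, columns=[f"f{i}" for i in range(np.shape(X)[1])])
    return X - X.mean()


class TestFitPls:
    def test_noiseless_collinear_system_exact_with_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        X = _centered(np.outer(t, [1.0, -2.0, 0.5]))
        y = 3.0 * t
        m = fit_pls(X, y, 1)
        assert np.sqrt(np.mean((m.predict_scaled(X) - y) ** 2)) < 1e-8

    def test_full_rank_pls_equals_ols(self):
        """Oracle equivalence: with a = p on full-rank data PLS reproduces
        ordinary least squares."""
        rng = np.random.default_rng(1)
        X = _centered(rng.normal(size=(25, 5)))
        y = rng.normal(size=25)
        m = fit_pls(X, y, 5)
        A = np.c_[np.ones(25), X.to_numpy()]
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.max(np.abs(m.predict_scaled(X) - A @ beta)) < 1e-8

    def test_matches_reference_pls_implementation(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        X = _centered(rng.normal(size=(30, 6)))
        y = rng.normal(size=30)
        for a in (1, 3, 6):
            mine = fit_pls(X, y, a).predict_scaled(X)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y).predict(X.to_numpy())
            assert np.max(np.abs(mine - ref.ravel())) < 1e-10

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = _centered(rng.normal(size=(20, 4)))
        y = rng.normal(size=20)
        m = fit_pls(X, y, 2)
        perm = ["f2", "f0", "f3", "f1"]
        m2 = fit_pls(X[perm], y, 2)
        assert np.max(np.abs(m.predict_scaled(X) - m2.predict_scaled(X[perm]))) < 1e-10

    def test_rank_deficient_names_achievable_components(self):
        t = np.arange(10.0)
        X = _centered(np.outer(t, [1.0, 2.0, 3.0]))  # rank 1
        with pytest.raises(ValidationError, match="supports only 1"):
            fit_pls(X, t, 3)


class TestSelectComponents:
    def test_planted_two_dimensional_signal_recovered(self):
        """CV component selection finds the planted latent dimension in at
        least 8 of 10 seeded repetitions."""
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            T = rng.normal(size=(100, 2))
            X = _centered(T @ rng.normal(size=(2, 8)) + 0.05 * rng.normal(size=(100, 8)))
            y = T @ [1.0, -0.7] + 0.05 * rng.normal(size=100)
            a, _ = select_components(X, y, folds=10, a_grid=tuple(range(1, 7)), seed=s)
            hits += a == 2
        assert hits >= 8

    def test_singleton_grid(self):
        rng = np.random.default_rng(0)
        X = _centered(rng.normal(size=(20, 4)))
        a, _ = select_components(X, rng.normal(size=20), a_grid=(1,), seed=0)
        assert a == 1

    def test_chosen_a_minimises_returned_table(self):
        rng = np.random.default_rng(5)
        X = _centered(rng.normal(size=(30, 5)))
        y = X["f0"].to_numpy() + 0.1 * rng.normal(size=30)
        a, table = select_components(X, y, seed=1)
        best = table.loc[table["a"] == a, "rmsep"].iloc[0]
        assert (best <= table["rmsep"] + 1e-15).all()


class TestDoubleStep:
    def test_three_regressors_with_recorded_components(self, fitted_models):
        _, model_a, _ = fitted_models
        assert set(model_a.regressors) == set(LANDFILL_CLASSES)
        assert all(a >= 1 for a in model_a.components.values())

    def test_single_class_training_set_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        ts = TrainingSet(
            X=X,
            y_class=pd.Series([LEACHATE] * 20, index=X.index),
            y_logc=pd.Series(rng.uniform(1.5, 2.5, 20), index=X.index),
            scaler_mean=X.mean(),
            scaler_sd=X.std(ddof=1),
        )
        with pytest.raises(ValidationError, match=">= 2 odorous classes"):
            fit_double_step(ts, seed=0)

    def test_routing_is_bit_identical_to_routed_regressor(self, fitted_models, training_set):
        _, model_a, _ = fitted_models
        for _, row in training_set.X.head(30).iterrows():
            res = model_a.predict(row)
            if res.label == AIR:
                continue
            direct = model_a.regressors[res.label].predict_scaled(model_a._scale(row))[0]
            assert res.detail["raw_log10"] == direct
            assert res.detail["routed_to"] == res.label

    def test_air_short_circuits_quantification(self, fitted_models, training_set):
        _, model_a, _ = fitted_models
        air_rows = training_set.X[training_set.y_class == AIR]
        res = model_a.predict(air_rows.iloc[0])
        assert res.label == AIR and res.concentration is None

    def test_per_class_fit_beats_global_on_class_rows(self, fitted_models, training_set):
        _, model_a, model_b = fitted_models
        odor = training_set.odorous()
        Xs = odor.X_scaled
        y = odor.y_logc.to_numpy()
        for cls in LANDFILL_CLASSES:
            rows = (odor.y_class == cls).to_numpy()
            ra = y[rows] - model_a.regressors[cls].predict_scaled(Xs.loc[rows])
            rb = y[rows] - model_b.pls.predict_scaled(Xs.loc[rows])
            r2 = lambda r: 1 - np.sum(r**2) / np.sum((y[rows] - y[rows].mean()) ** 2)
            assert r2(ra) > r2(rb), cls


class TestGlobalModel:
    def test_deterministic_component_choice(self, training_set):
        b1 = fit_global(training_set, seed=4)
        b2 = fit_global(training_set, seed=4)
        assert b1.pls.n_components == b2.pls.n_components
        pd.testing.assert_series_equal(b1.pls.coef, b2.pls.coef)

    def test_single_class_degenerate_equality_with_model_a(self):
        """On one-class data the global model and that class's routed
        regressor are the same regression (same rows, same a)."""
        params = simulate.fenceline_params(seed=21)
        samples, frames = simulate.simulate_training_campaign(params, seed=21)
        keep = [(s, f) for s, f in zip(samples, frames)
                if s.class_label in (AIR, LANDFILL_GAS)]
        fvs = [extract_features(f, sample_id=s.sample_id) for s, f in keep]
        ts = build_training_set([s for s, _ in keep], fvs)
        model_b = fit_global(ts, seed=0, pinned_components=3)
        odor = ts.odorous()
        reg = fit_pls(odor.X_scaled, odor.y_logc, 3)
        assert np.max(np.abs(reg.coef - model_b.pls.coef)) < 1e-8

    def test_double_step_cv_rmsep_not_worse_than_global(self, training_set):
        odor = training_set.odorous()
        _, tab_g = select_components(odor.X_scaled, odor.y_logc, a_grid=(3,), seed=0)
        worst_class = -np.inf
        for cls in LANDFILL_CLASSES:
            rows = odor.y_class == cls
            _, tab_c = select_components(
                odor.scale(odor.X[rows]), odor.y_logc[rows], a_grid=(3,), seed=0
            )
            worst_class = max(worst_class, tab_c["rmsep"].iloc[0])
        assert tab_g["rmsep"].iloc[0] >= worst_class


class TestPredictConcentration:
    def test_inverse_log_scale(self, fitted_models):
        _, model_a, _ = fitted_models
        reg = model_a.regressors[LEACHATE]
        # craft a scaled vector giving exactly yhat = 2
        c = reg.coef
        xs = reg.x_mean + c / (c @ c) * (2.0 - reg.y_mean)
        raw = xs * model_a.scaler_sd + model_a.scaler_mean
        yhat = reg.predict_scaled(model_a._scale(raw))[0]
        assert yhat == pytest.approx(2.0, abs=1e-9)
        assert 10 ** yhat == pytest.approx(100.0, rel=1e-8)

    def test_sub_unit_prediction_clipped_and_flagged(self, fitted_models):
        _, _, model_b = fitted_models
        reg = model_b.pls
        c = reg.coef
        xs = reg.x_mean + c / (c @ c) * (-3.0 - reg.y_mean)
        raw = xs * model_b.scaler_sd + model_b.scaler_mean
        res = model_b.predict(raw)
        assert res.clipped and res.concentration == 1.0

    def test_noiseless_generator_recovery_both_models(self):
        """On (near-)noiseless simulated data, both the routed and global
        models reproduce the true log10 concentration to < 1e-6."""
        params = simulate.fenceline_params(seed=31)
        tiny = {ch: 1e-9 for ch in params.noise_sd}
        params = simulate.SimParams(
            seed=31, schema=params.schema, baseline=params.baseline,
            noise_sd=tiny, humidity_gamma=params.humidity_gamma,
            fingerprints=params.fingerprints, detection_floor=params.detection_floor,
            rh_sd=0.0, dilutions_per_source=3,
        )
        samples, frames = simulate.simulate_training_campaign(params, seed=31)
        fvs = [extract_features(f, sample_id=s.sample_id) for s, f in zip(samples, frames)]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-zero variance features
            ts = build_training_set(samples, fvs)
            # drop the non-responsive channels: autoscaling would blow their
            # residual 1e-9 noise up to unit variance, which is not the
            # noiseless regime this invariant is about
            keep = ts.X.columns[ts.X.std(ddof=1) > 1e-6]
            X = ts.X[keep]
            ts = TrainingSet(X=X, y_class=ts.y_class, y_logc=ts.y_logc,
                             scaler_mean=X.mean(), scaler_sd=X.std(ddof=1))
            clf = KnnClassifier.fit(ts, 1)
            # noiseless geometry: each class line is 1-dimensional and the
            # three class directions span an exactly rank-3 odorous matrix
            model_a = fit_double_step(ts, clf, seed=0, pinned_components={c: 1 for c in LANDFILL_CLASSES})
            model_b = fit_global(ts, seed=0, pinned_components=3)
        for s, fv in list(zip(samples, fvs))[::5]:
            if s.is_air:
                continue
            truth = np.log10(s.concentration)
            ra = predict_concentration(model_a, fv.features)
            rb = predict_concentration(model_b, fv.features)
            assert abs(ra.log10_concentration - truth) < 1e-6
            assert abs(rb.log10_concentration - truth) < 1e-6


class TestResidualDiagnostics:
    def test_gaussian_residuals_pass_normality(self, fitted_models, training_set):
        _, model_a, _ = fitted_models
        rep = residual_diagnostics(model_a, training_set)
        assert rep.shapiro_p > 0.01
        assert rep.flags["normality"] == "pass"

    def test_planted_heteroscedasticity_flagged(self, training_set):
        """Residual variance proportional to the fitted value must raise the
        heteroscedasticity flag."""
        model_b = fit_global(training_set, seed=0)
        odor = training_set.odorous()
        rng = np.random.default_rng(0)
        fitted = model_b.pls.predict_scaled(odor.X_scaled)
        y_fake = fitted + rng.normal(size=len(fitted)) * 0.5 * (fitted - fitted.min())
        ts2 = TrainingSet(
            X=odor.X, y_class=odor.y_class,
            y_logc=pd.Series(y_fake, index=odor.X.index),
            scaler_mean=training_set.scaler_mean, scaler_sd=training_set.scaler_sd,
        )
        rep = residual_diagnostics(model_b, ts2)
        assert rep.flags["homoscedasticity"] == "warn"

    def test_perfect_fit_reported_degenerate(self, training_set):
        model_b = fit_global(training_set, seed=0)
        odor = training_set.odorous()
        y_exact = pd.Series(
            model_b.pls.predict_scaled(odor.X_scaled), index=odor.X.index
        )
        ts2 = TrainingSet(
            X=odor.X, y_class=odor.y_class, y_logc=y_exact,
            scaler_mean=training_set.scaler_mean, scaler_sd=training_set.scaler_sd,
        )
        rep = residual_diagnostics(model_b, ts2)
        assert rep.degenerate


class TestEstimateLdl:
    def test_planted_floor_recovered(self, campaign, training_set):
        """Channel floors at 50 odor units: grid {40, 50, 60} yields LDL 50."""
        params, _, _ = campaign
        air_X = training_set.X[training_set.y_class == AIR]
        series = []
        for ci, cls in enumerate(LANDFILL_CLASSES):
            for li, conc in enumerate((40.0, 50.0, 60.0)):
                for rep in range(3):
                    f = simulate.simulate_sample_response(
                        cls, conc, params, seed=9000 + 100 * ci + 10 * li + rep
                    )
                    series.append((cls, conc, extract_features(f).features))
        ldl = estimate_ldl(series, air_X)
        for cls in LANDFILL_CLASSES:
            assert ldl[cls].value == 50.0, cls
            assert not ldl[cls].censored

    def test_air_self_exceedance_near_quantile(self, training_set):
        from odormon.quantify import air_neutrality_envelope

        air_X = training_set.X[training_set.y_class == AIR]
        distance, envelope, _ = air_neutrality_envelope(air_X, quantile=0.99)
        exceed = np.mean([distance(row) > envelope for _, row in air_X.iterrows()])
        # by definition of the 99th-percentile envelope ~1% of the air
        # replicates lie outside it
        assert exceed <= 0.05

    def test_too_few_air_rows_rejected(self, training_set):
        air_X = training_set.X[training_set.y_class == AIR].head(5)
        with pytest.raises(ValidationError, match=">= 10 air"):
            estimate_ldl([], air_X)

    def test_lcl_not_below_ldl_on_consistent_input(self, campaign, training_set, fitted_models):
        """A sample must be detected before it can be classified: on the same
        dilution grid the classification limit is >= the detection limit."""
        from odormon.classify import estimate_lcl

        params, _, _ = campaign
        clf, model_a, _ = fitted_models
        air_X = training_set.X[training_set.y_class == AIR]
        series, lcl_rows = [], []
        for ci, cls in enumerate(LANDFILL_CLASSES):
            for li, conc in enumerate((40.0, 50.0, 60.0, 80.0)):
                for rep in range(2):
                    f = simulate.simulate_sample_response(
                        cls, conc, params, seed=11000 + 997 * ci + 31 * li + rep
                    )
                    fv = extract_features(f).features
                    series.append((cls, conc, fv))
                    lcl_rows.append((cls, conc, clf.predict(fv)[0]))
        ldl = estimate_ldl(series, air_X)
        lcl = estimate_lcl(lcl_rows)
        for cls in LANDFILL_CLASSES:
            if ldl[cls].value is not None and lcl[cls].value is not None:
                assert lcl[cls].value >= ldl[cls].value
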