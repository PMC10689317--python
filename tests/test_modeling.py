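"""Model-construction stages: cleaning, redundancy filtering, LASSO-Cox
selection, backward elimination, VIF, Cox fitting, splitting, fusion."""

import numpy as np
import pandas as pd
import pytest

from radsurv.modeling import (
    backward_eliminate,
    breslow_loglik,
    build_combined_model,
    clean_features,
    combined_design,
    fit_cox,
    lasso_cox_select,
    pearson_redundancy_filter,
    split_cohort,
    vif_check,
)
from radsurv.synthetic import generate_survival


def _informative_dataset(seed, n=200, p=50, beta_idx=(0, 1), beta_val=1.0,
                         censor=0.3, h0=0.02):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"f{i}" for i in range(p)])
    beta = np.zeros(p)
    for i in beta_idx:
        beta[i] = beta_val
    t, e = generate_survival(X.to_numpy(), h0, beta, censor_rate=censor,
                             seed=np.random.default_rng(seed + 777))
    return X, t, e


class TestCleaning:
    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        clean, dropped = clean_features(df)
        assert dropped == ["b"] and list(clean.columns) == ["a"]

    def test_duplicate_column_single_retained(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=10)})
        clean, dropped = clean_features(df)
        assert dropped == ["b"] and list(clean.columns) == ["a", "c"]

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        once, _ = clean_features(df)
        twice, dropped = clean_features(once)
        assert dropped == [] and twice.equals(once)

    def test_missing_values_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=5), "b": [1.0, np.nan, 2, 3, 4]})
        _, dropped = clean_features(df)
        assert dropped == ["b"]


class TestRedundancyFilter:
    def test_exact_multiple_dropped(self, rng):
        a = rng.normal(size=30)
        df = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.normal(size=30)})
        kept, dropped = pearson_redundancy_filter(df)
        assert dropped == ["B"] and list(kept.columns) == ["A", "C"]

    def test_independent_features_survive(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((500, 20)))
        df.columns = [f"x{i}" for i in range(20)]
        _, dropped = pearson_redundancy_filter(df)
        assert dropped == []

    def test_rescaling_invariant(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        df["dup"] = df["a"] * 0.9 + rng.normal(0, 0.01, 40)
        k1, d1 = pearson_redundancy_filter(df)
        scaled = df * np.array([1, 100, 0.01, 7, 3, 2.5])
        k2, d2 = pearson_redundancy_filter(scaled)
        assert d1 == d2 and list(k1.columns) == list(k2.columns)


class TestLassoCox:
    def test_informative_features_selected(self):
        X, t, e = _informative_dataset(seed=4)
        sel = lasso_cox_select(X, t, e, folds=10, seed=0)
        assert {"f0", "f1"} <= set(sel.active)
        assert sel.lambda_min > 0

    def test_duplicate_informative_feature_l1_behavior(self):
        X, t, e = _informative_dataset(seed=5, p=20)
        X["f0_dup"] = X["f0"]
        sel = lasso_cox_select(X, t, e, folds=5, seed=0)
        got = {"f0", "f0_dup"} & set(sel.active)
        assert len(got) >= 1  # at least one of the L1-tied pair is active

    def test_deterministic_given_seed(self):
        X, t, e = _informative_dataset(seed=6, n=120, p=20)
        s1 = lasso_cox_select(X, t, e, seed=3)
        s2 = lasso_cox_select(X, t, e, seed=3)
        assert s1.active == s2.active and s1.lambda_min == s2.lambda_min

    def test_requires_events(self):
        X, t, _ = _informative_dataset(seed=7, n=30, p=3)
        with pytest.raises(ValueError, match="event"):
            lasso_cox_select(X, t, np.zeros(30, dtype=int))

    def test_breslow_loglik_zero_eta(self):
        # with eta = 0, l = -sum over events of log |risk set|
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 1, 1])
        expected = -(np.log(3) + np.log(2) + np.log(1))
        assert breslow_loglik(t, e, np.zeros(3)) == pytest.approx(expected)


class TestBackwardElimination:
    def test_strong_features_retained(self):
        X, t, e = _informative_dataset(seed=8, p=2)
        feats = backward_eliminate(X, t, e, ["f0", "f1"])
        assert feats == ["f0", "f1"]

    def test_noise_feature_removed(self):
        removed = 0
        for seed in range(20):
            X, t, e = _informative_dataset(seed=seed, n=150, p=3, beta_idx=(0, 1))
            feats = backward_eliminate(X, t, e, ["f0", "f1", "f2"])
            if "f2" not in feats:
                removed += 1
        assert removed >= 18  # pure-noise covariate eliminated in >= 90%

    def test_deterministic_order(self):
        X, t, e = _informative_dataset(seed=9, n=100, p=6)
        f1 = backward_eliminate(X, t, e, list(X.columns))
        f2 = backward_eliminate(X, t, e, list(X.columns))
        assert f1 == f2


class TestVIF:
    def test_orthogonal_features_unit_vif(self):
        # zero-mean columns with zero cross-products (Hadamard design)
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1],
                          "c": [1, -1, -1, 1]}, dtype=float)
        report = vif_check(X)
        assert np.allclose(report["vif"], 1.0)
        assert not report["flagged"].any()

    def test_near_collinear_flagged(self, rng):
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1e-4, 50),
                          "c": rng.normal(size=50)})
        report = vif_check(X).set_index("feature")
        assert report.loc["a", "vif"] > 5 and report.loc["a", "flagged"]

    def test_matches_direct_r2_regressions(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        X["b"] += 0.7 * X["a"]
        report = vif_check(X).set_index("feature")
        import statsmodels.api as sm

        for col in X.columns:
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert report.loc[col, "vif"] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestFitCox:
    def test_binary_covariate_consistency(self):
        rng = np.random.default_rng(10)
        x = rng.integers(0, 2, 2000).astype(float)
        t, e = generate_survival(x[:, None], 0.05, [np.log(2)], seed=rng)
        X = pd.DataFrame({"x": x})
        model = fit_cox(X, t, e)
        # coefficient is on the standardized scale; undo the scaling
        beta_raw = model.coefficients["x"] / model.scale["x"]
        # SE of log HR ~ sqrt(4/n_events) for a balanced binary covariate
        se = np.sqrt(4 / e.sum())
        assert abs(beta_raw - np.log(2)) < 3 * se

    def test_affine_rescaling_leaves_predictions(self):
        X, t, e = _informative_dataset(seed=11, n=100, p=3)
        m1 = fit_cox(X, t, e)
        X2 = X.copy()
        X2["f0"] = X2["f0"] * 10 + 5
        m2 = fit_cox(X2, t, e)
        assert np.allclose(m1.linear_predictor(X), m2.linear_predictor(X2), atol=1e-6)

    def test_empty_feature_model_scores_zero(self):
        X, t, e = _informative_dataset(seed=12, n=50, p=2)
        model = fit_cox(X, t, e, features=[])
        assert model.linear_predictor(X).tolist() == [0.0] * 50
        assert model.provenance.get("empty")

    def test_cutoff_is_training_median(self):
        X, t, e = _informative_dataset(seed=13, n=100, p=2)
        model = fit_cox(X, t, e)
        assert model.cutoff == pytest.approx(np.median(model.linear_predictor(X)))

    def test_serialization_round_trip(self):
        from radsurv.modeling import SurvivalModel

        X, t, e = _informative_dataset(seed=14, n=80, p=3)
        model = fit_cox(X, t, e)
        back = SurvivalModel.from_dict(model.to_dict())
        assert np.allclose(back.linear_predictor(X), model.linear_predictor(X))


class TestSplit:
    def test_sizes_and_determinism(self):
        X, t, e = _informative_dataset(seed=15, n=100, p=2)
        tr1, te1 = split_cohort(t, e, 0.7, seed=5)
        tr2, te2 = split_cohort(t, e, 0.7, seed=5)
        assert tr1.sum() == 70 and te1.sum() == 30
        assert np.array_equal(tr1, tr2)

    def test_event_fraction_stratified(self):
        X, t, e = _informative_dataset(seed=16, n=200, p=2, censor=0.4)
        tr, te = split_cohort(t, e, 0.7, seed=0)
        f_tr = e[tr].mean()
        f_te = e[te].mean()
        # stratification keeps the event fractions within one subject of equal
        assert abs(e[tr].sum() - round(0.7 * e.sum())) <= 1
        assert abs(f_tr - f_te) < 0.1


class TestCombinedModel:
    def _mr_model(self, seed=17, n=200):
        X, t, e = _informative_dataset(seed=seed, n=n, p=10, beta_idx=(0,))
        model = fit_cox(X, t, e, features=["f0"])
        return model, X, t, e

    def test_dce_duplicates_of_mr_prediction_degenerate(self):
        mr, X, t, e = self._mr_model()
        pred = mr.linear_predictor(X)
        dce = pd.DataFrame({"d0": pred, "d1": 2 * pred + 1})
        combined = build_combined_model(mr, X, dce, t, e)
        assert combined.provenance.get("combined_degenerate")
        assert combined.features == mr.features
        assert np.allclose(combined.linear_predictor(X), mr.linear_predictor(X))

    def test_mr_prediction_survives_when_dominant(self):
        mr, X, t, e = self._mr_model()
        rng = np.random.default_rng(0)
        dce = pd.DataFrame(rng.standard_normal((len(X), 5)),
                           columns=[f"d{i}" for i in range(5)], index=X.index)
        combined = build_combined_model(mr, X, dce, t, e, seed=1)
        assert "MR_prediction" in combined.features

    def test_combined_design_adds_prediction_column(self):
        mr, X, t, e = self._mr_model()
        rng = np.random.default_rng(1)
        dce = pd.DataFrame(rng.standard_normal((len(X), 3)),
                           columns=list("pqr"), index=X.index)
        design = combined_design(mr, X, dce)
        assert "MR_prediction" in design.columns
        assert np.allclose(design["MR_prediction"], mr.linear_predictor(X))
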