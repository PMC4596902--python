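"""VIF pruning, Fisher LDA with diagnostics, and the counting pipeline."""

import math

import numpy as np
import pandas as pd
import pytest

from tillercount import classify, synthetic


def _gaussian_training(rng, n=2000, delta=(4.0, 0.0)):
    """Two spherical Gaussian classes in 2-D separated along the x axis."""
    a = rng.standard_normal((n, 2)) + np.asarray(delta)
    b = rng.standard_normal((n, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["x1", "x2"])
    y = np.array([classify.SHOOT] * n + [classify.NON_SHOOT] * n)
    return X, y


class TestVIF:
    def test_orthogonal_centered_features_have_unit_vif(self):
        # trig columns: exactly zero-mean and mutually orthogonal
        t = np.arange(64)
        X = pd.DataFrame({
            "c1": np.cos(2 * np.pi * t / 64), "s1": np.sin(2 * np.pi * t / 64),
            "c2": np.cos(4 * np.pi * t / 64), "s2": np.sin(4 * np.pi * t / 64),
        })
        vif = classify.compute_vif(X)
        np.testing.assert_allclose(vif, 1.0, atol=1e-6)

    def test_correlated_pair_matches_closed_form(self, rng):
        n = 10_000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": rng.standard_normal(n)})
        vif = classify.compute_vif(X)
        assert vif["x1"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
        assert vif["x2"] == pytest.approx(1 / (1 - 0.81), rel=0.05)
        assert vif["x3"] == pytest.approx(1.0, abs=0.05)

    def test_exact_collinearity_reported_as_infinity(self, rng):
        x1, x2 = rng.standard_normal((2, 200))
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
        assert np.isinf(classify.compute_vif(X)).all()

    def test_agrees_with_statsmodels_on_well_conditioned_data(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = pd.DataFrame(rng.standard_normal((500, 4)) @ np.triu(np.ones((4, 4))),
                         columns=list("abcd"))
        ours = classify.compute_vif(X)
        design = sm.add_constant(X).to_numpy()
        theirs = [variance_inflation_factor(design, j) for j in range(1, 5)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)


class TestVIFPrune:
    def test_orthogonal_set_is_untouched(self, rng):
        X = pd.DataFrame(rng.standard_normal((300, 5)),
                         columns=list("abcde"))
        survivors, trace = classify.vif_prune(X)
        assert survivors == list("abcde")
        assert len(trace) == 0

    def test_duplicate_column_prunes_exactly_one_of_the_pair(self, rng):
        x = rng.standard_normal(300)
        X = pd.DataFrame({"a": x, "b": rng.standard_normal(300),
                          "a_copy": x + 1e-13 * rng.standard_normal(300)})
        survivors, trace = classify.vif_prune(X)
        assert len(trace) == 1
        assert {"a", "a_copy"} - set(survivors) == {trace["feature"].iloc[0]}
        assert (classify.compute_vif(X[survivors]) <= 10).all()

    def test_collinear_block_deleted_before_weakly_correlated_features(self, rng):
        # emulate the perimeter/diameter block: FD_max and P_conv track a
        # common latent size almost exactly, other descriptors only loosely
        n = 4000
        size = rng.lognormal(3.0, 0.4, n)
        X = pd.DataFrame({
            "A": size**2 * (1 + 0.2 * rng.standard_normal(n)),
            "CMA": rng.standard_normal(n),
            "FD_max": size * (1 + 0.01 * rng.standard_normal(n)),
            "P_conv": math.pi * size * (1 + 0.01 * rng.standard_normal(n)),
            "SF_elong": rng.standard_normal(n) + 0.1 * size,
        })
        survivors, trace = classify.vif_prune(X)
        assert set(trace["feature"][:1]) <= {"FD_max", "P_conv"}
        assert (classify.compute_vif(X[survivors]) <= 10).all()

    def test_over_pruning_raises(self, rng):
        x = rng.standard_normal(100)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": -x})
        with pytest.raises(ValueError, match="over-pruned"):
            classify.vif_prune(X, threshold=1.01)


class TestFitLDA:
    def test_recovers_population_discriminant_direction(self, rng):
        X, y = _gaussian_training(rng, n=5000)
        model = classify.fit_lda(X, y, stepwise=False)
        w = model.coef / np.linalg.norm(model.coef)
        angle = math.degrees(math.acos(abs(w[0])))
        assert angle < 5.0

    def test_identical_classes_give_lambda_near_one(self, rng):
        X, y = _gaussian_training(rng, n=2000, delta=(0.0, 0.0))
        model = classify.fit_lda(X, y, stepwise=False)
        assert model.wilks_lambda == pytest.approx(1.0, abs=0.01)
        labels, e = classify.classify_objects(model, X)
        assert 0.4 < e / len(X) < 0.6

    def test_row_order_does_not_change_coefficients(self, rng):
        X, y = _gaussian_training(rng, n=500)
        model = classify.fit_lda(X, y, stepwise=False)
        perm = rng.permutation(len(X))
        model2 = classify.fit_lda(X.iloc[perm].reset_index(drop=True), y[perm],
                                  stepwise=False)
        np.testing.assert_allclose(model2.coef, model.coef, rtol=1e-8)
        assert model2.intercept == pytest.approx(model.intercept, rel=1e-8)

    def test_rescaling_one_feature_leaves_labels_unchanged(self, rng):
        X, y = _gaussian_training(rng, n=1000)
        model = classify.fit_lda(X, y, stepwise=False)
        Xs = X.assign(x1=X["x1"] * 37.0)
        model_s = classify.fit_lda(Xs, y, stepwise=False)
        l1, _ = classify.classify_objects(model, X)
        l2, _ = classify.classify_objects(model_s, Xs)
        assert (l1 == l2).mean() > 0.999

    def test_agrees_with_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = _gaussian_training(rng, n=1000)
        model = classify.fit_lda(X, y, stepwise=False)
        sk = LinearDiscriminantAnalysis().fit(X, y == classify.SHOOT)
        # same direction up to scale
        ratio = model.coef / sk.coef_.ravel()
        assert ratio.std() / abs(ratio.mean()) < 1e-6
        ours, _ = classify.classify_objects(model, X)
        theirs = sk.predict(X)
        assert ((ours == classify.SHOOT) == theirs).mean() > 0.999

    def test_singular_covariance_advises_pruning(self, rng):
        x = rng.standard_normal(200)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = np.array([classify.SHOOT, classify.NON_SHOOT] * 100)
        with pytest.raises(ValueError, match="prune"):
            classify.fit_lda(X, y, stepwise=False)


class TestDiagnostics:
    def test_uninformative_variable_has_smallest_f_to_remove(self, rng):
        n = 3000
        X = pd.DataFrame({
            "informative": np.r_[rng.standard_normal(n) + 2,
                                 rng.standard_normal(n)],
            "noise1": rng.standard_normal(2 * n),
            "noise2": rng.standard_normal(2 * n),
        })
        y = np.array([classify.SHOOT] * n + [classify.NON_SHOOT] * n)
        diag = classify.lda_diagnostics(X, y)
        assert diag["F"].idxmax() == "informative"
        assert diag.loc["noise1", "F"] < 5
        # removing a pure-noise variable leaves Wilks' lambda unchanged
        lam_full = classify.fit_lda(X, y, stepwise=False).wilks_lambda
        assert diag.loc["noise1", "Lambda"] == pytest.approx(lam_full, rel=0.01)

    def test_duplicated_variable_sends_tolerance_to_zero(self, rng):
        x = rng.standard_normal(400)
        X = pd.DataFrame({"a": x, "b": x + 1e-10 * rng.standard_normal(400),
                          "c": rng.standard_normal(400)})
        y = np.array([classify.SHOOT, classify.NON_SHOOT] * 200)
        diag = classify.lda_diagnostics(X, y)
        assert diag.loc["a", "T"] < 1e-6

    def test_tolerance_and_lambda_in_unit_interval(self, rng):
        X, y = _gaussian_training(rng, n=400)
        diag = classify.lda_diagnostics(X, y)
        assert ((diag["T"] > 0) & (diag["T"] <= 1)).all()
        assert ((diag["Lambda"] > 0) & (diag["Lambda"] <= 1)).all()

    def test_stepwise_drops_noise_keeps_signal(self, rng):
        n = 2000
        X = pd.DataFrame({
            "signal": np.r_[rng.standard_normal(n) + 3, rng.standard_normal(n)],
            "noise": rng.standard_normal(2 * n),
            "noise2": rng.standard_normal(2 * n),
            "noise3": rng.standard_normal(2 * n),
        })
        y = np.array([classify.SHOOT] * n + [classify.NON_SHOOT] * n)
        model = classify.fit_lda(X, y, stepwise=True, min_features=1)
        assert "signal" in model.features
        assert len(model.features) < 4


class TestClassifyAndCount:
    def _toy_model(self):
        return classify.ShootClassifier(
            features=["SF_elong"], coef=np.array([-1.0]), intercept=0.5,
            priors=(0.5, 0.5), diagnostics=pd.DataFrame(),
        )

    def test_empty_table_counts_zero(self):
        labels, e = classify.classify_objects(self._toy_model(), pd.DataFrame())
        assert e == 0 and len(labels) == 0

    def test_boundary_ties_resolve_to_shoot(self):
        feats = pd.DataFrame({"SF_elong": [0.5, 0.6]})  # scores 0 and -0.1
        labels, e = classify.classify_objects(self._toy_model(), feats)
        assert list(labels) == [classify.SHOOT, classify.NON_SHOOT]
        assert e == 1

    def test_missing_feature_column_is_named(self):
        with pytest.raises(ValueError, match="SF_elong"):
            classify.classify_objects(self._toy_model(),
                                      pd.DataFrame({"A": [1.0]}))

    def test_model_json_round_trip(self, tmp_path, rng):
        X, y = _gaussian_training(rng, n=300)
        model = classify.fit_lda(X, y, stepwise=False, species="round_thick")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = classify.ShootClassifier.from_json(path)
        np.testing.assert_allclose(back.coef, model.coef)
        assert back.features == model.features
        assert back.species == "round_thick"
        l1, _ = classify.classify_objects(model, X)
        l2, _ = classify.classify_objects(back, X)
        assert (l1 == l2).all()

    def test_count_tillers_is_deterministic_and_counts_scene(self, tmp_path):
        spec = synthetic.SceneSpec(seed=42, size=(900, 900), n_tips=60,
                                   n_leaf_fragments=15, n_debris=20)
        image, truth = synthetic.render_scene(spec)
        feats, _ = synthetic._segment_and_describe(image, truth)
        X = feats[[c for c in feats.columns
                   if c not in ("id", "class", "truth_cls")]]
        survivors, trace = classify.vif_prune(X)
        model = classify.fit_lda(X[survivors], feats["class"].to_numpy(),
                                 vif_trace=trace)
        import imageio.v3 as iio

        path = tmp_path / "scene.png"
        iio.imwrite(path, image)
        report1 = classify.count_tillers(path, model)
        report2 = classify.count_tillers(path, model)
        assert report1 == report2
        assert abs(report1["E"] - truth.O) <= 0.1 * truth.O

    def test_blank_soil_image_counts_zero(self, tmp_path):
        import imageio.v3 as iio

        spec = synthetic.SceneSpec(seed=9, size=(700, 700), n_tips=0,
                                   n_leaf_fragments=0, n_debris=0)
        image, _ = synthetic.render_scene(spec)
        path = tmp_path / "soil.png"
        iio.imwrite(path, image)
        report = classify.count_tillers(path, self._toy_model())
        assert report["E"] == 0
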