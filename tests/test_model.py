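"""Core model: standardization, term scores, ALS fitting, prediction."""
import numpy as np
import pytest
import statsmodels.api as sm

from eracv.model import (
    BlockSpec,
    DegenerateColumnError,
    DegenerateResponseError,
    ERAError,
    ERAParameters,
    FitOptions,
    InsufficientDataError,
    ModelSpec,
    Term,
    apply_standardization,
    compute_term_scores,
    era_objective,
    fit_era,
    fit_metric,
    predict,
    rmse,
    standardize_fit,
)


class TestSpecs:
    def test_block_spec_rejects_overlap(self):
        with pytest.raises(ERAError, match="more than one block"):
            BlockSpec([("a", (0, 1)), ("b", (1, 2))])

    def test_block_spec_rejects_empty_block(self):
        with pytest.raises(ERAError, match="empty"):
            BlockSpec([("a", ())])

    def test_model_spec_requires_linear_term_per_block(self):
        bs = BlockSpec([("a", (0,)), ("b", (1,))])
        with pytest.raises(ERAError, match="linear term"):
            ModelSpec(bs, [Term("linear", "a"), Term("interaction", "a", "b")])

    def test_model_spec_rejects_duplicates_and_unknown_blocks(self):
        bs = BlockSpec([("a", (0,)), ("b", (1,))])
        with pytest.raises(ERAError, match="duplicate"):
            ModelSpec(bs, [Term("linear", "a"), Term("linear", "b"), Term("linear", "a")])
        with pytest.raises(ERAError, match="unknown block"):
            ModelSpec(bs, [Term("linear", "a"), Term("linear", "b"), Term("quadratic", "zzz")])

    def test_interaction_blocks_canonically_ordered(self):
        bs = BlockSpec([("a", (0,)), ("b", (1,))])
        spec = ModelSpec(
            bs, [Term("linear", "a"), Term("linear", "b"), Term("interaction", "b", "a")]
        )
        assert spec.terms[-1] == Term("interaction", "a", "b")


class TestStandardization:
    def test_hand_example_column_123(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        Z, y_c, params = standardize_fit(X, y)
        assert params.mean[0] == pytest.approx(2.0)
        assert params.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))
        np.testing.assert_allclose(Z[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)
        np.testing.assert_allclose(y_c, [-1.0, 0.0, 1.0])

    def test_already_standardized_column_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std()  # divisor-N standardization
        X = x[:, None]
        Z, _, _ = standardize_fit(X, rng.standard_normal(200))
        np.testing.assert_allclose(Z[:, 0], x, atol=1e-12)

    def test_constant_column_raises_with_column_name(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.raises(DegenerateColumnError, match=r"\[1\]"):
            standardize_fit(X, np.arange(5.0))

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            standardize_fit(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]))

    def test_apply_uses_training_params(self):
        X = np.array([[1.0], [2.0], [3.0]])
        _, _, params = standardize_fit(X, np.zeros(3))
        # new value 3 with training mean 2, sd 0.8165 -> z = 1.2247
        z = apply_standardization(np.array([[3.0]]), params)
        assert z[0, 0] == pytest.approx(1.2247, abs=1e-4)
        # a row at the training means maps to zeros
        np.testing.assert_allclose(apply_standardization(np.array([[2.0]]), params), 0.0)

    def test_apply_column_mismatch(self):
        _, _, params = standardize_fit(np.arange(6.0).reshape(3, 2), np.zeros(3))
        with pytest.raises(ERAError, match="columns"):
            apply_standardization(np.ones((2, 3)), params)


class TestTermScores:
    def test_hand_matrix_product(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        bs = BlockSpec([("a", (0, 1))])
        spec = ModelSpec(bs, [Term("linear", "a")])
        params = ERAParameters(weights={"a": np.array([0.6, 0.8])}, b=np.array([1.0]))
        F, T = compute_term_scores(Z, params, spec)
        np.testing.assert_allclose(F[:, 0], [0.6, 0.8, -1.4])
        np.testing.assert_allclose(T[:, 0], F[:, 0])

    def test_interaction_is_elementwise_product(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((10, 2))
        bs = BlockSpec([("a", (0,)), ("b", (1,))])
        spec = ModelSpec(
            bs, [Term("linear", "a"), Term("linear", "b"), Term("interaction", "a", "b")]
        )
        params = ERAParameters(
            weights={"a": np.array([1.0]), "b": np.array([1.0])}, b=np.zeros(3)
        )
        _, T = compute_term_scores(Z, params, spec)
        np.testing.assert_allclose(T[:, 2], Z[:, 0] * Z[:, 1])

    def test_quadratic_is_elementwise_square(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((8, 1))
        bs = BlockSpec([("a", (0,))])
        spec = ModelSpec(bs, [Term("linear", "a"), Term("quadratic", "a")])
        params = ERAParameters(weights={"a": np.array([1.0])}, b=np.zeros(2))
        _, T = compute_term_scores(Z, params, spec)
        np.testing.assert_allclose(T[:, 1], Z[:, 0] ** 2)


class TestObjectiveAndRMSE:
    def test_objective_examples(self):
        y_c = np.array([1.0, -1.0, 0.0])
        T = np.eye(3)
        assert era_objective(y_c, T, np.zeros(3)) == pytest.approx(float(y_c @ y_c))
        assert era_objective(y_c, T, y_c) == pytest.approx(0.0)
        # fitted values (0.5, -0.5, 0) -> phi = 0.25 + 0.25 = 0.5
        assert era_objective(y_c, T, np.array([0.5, -0.5, 0.0])) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "y,y_hat,expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
            ((1.0, 2.0), (1.5, 2.5), 0.5),
            ((1.0, 2.0, 3.0), (1.0, 1.0, 5.0), np.sqrt(5.0 / 3.0)),
        ],
    )
    def test_rmse_examples(self, y, y_hat, expected):
        assert rmse(np.array(y), np.array(y_hat)) == pytest.approx(expected, abs=1e-10)

    def test_rmse_empty_raises(self):
        with pytest.raises(ERAError):
            rmse(np.array([]), np.array([]))


class TestFitEra:
    def test_degenerates_to_ols_with_single_predictor_blocks(self, single_pred_spec, make_data):
        X, y = make_data(n=40, p=2, seed=3)
        res = fit_era(y, X, single_pred_spec)
        Z, y_c, _ = standardize_fit(X, y)
        ols = sm.OLS(y_c, Z).fit()
        got = np.array(
            [res.params.weights["a"][0] * res.params.b[0],
             res.params.weights["b"][0] * res.params.b[1]]
        )
        np.testing.assert_allclose(got, ols.params, atol=1e-8)
        assert res.fit == pytest.approx(ols.rsquared, abs=1e-8)

    def test_component_scale_constraint(self, two_block_spec, make_data):
        X, y = make_data(n=60, p=4, seed=4)
        res = fit_era(y, X, two_block_spec)
        n = len(y)
        gram = res.F.T @ res.F
        np.testing.assert_allclose(np.diag(gram), n, atol=1e-6 * n)

    def test_objective_trace_non_increasing_over_random_instances(self):
        rng = np.random.default_rng(11)
        bs = BlockSpec([("a", (0, 1)), ("b", (2, 3))])
        base = [Term("linear", "a"), Term("linear", "b")]
        variants = [
            base,
            base + [Term("interaction", "a", "b")],
            base + [Term("interaction", "a", "b"), Term("quadratic", "a"), Term("quadratic", "b")],
        ]
        for i in range(100):
            n = int(rng.integers(20, 60))
            X = rng.standard_normal((n, 4))
            y = X @ rng.standard_normal(4) * 0.5 + rng.standard_normal(n)
            spec = ModelSpec(bs, variants[i % 3])
            res = fit_era(y, X, spec)
            diffs = np.diff(res.objective_trace)
            assert (diffs <= 1e-9 * max(res.objective_trace[0], 1.0)).all()
            assert res.phi >= 0

    def test_fit_identity_with_rmse(self, two_block_spec, make_data):
        X, y = make_data(n=45, p=4, seed=5)
        res = fit_era(y, X, two_block_spec)
        n = len(y)
        ss = float(((y - y.mean()) ** 2).sum())
        assert res.fit == pytest.approx(1.0 - n * res.rmse_train**2 / ss, abs=1e-10)
        assert fit_metric(res, y - y.mean()) == pytest.approx(res.fit, abs=1e-12)

    def test_fit_bounds(self, two_block_spec, make_data):
        X, y = make_data(n=45, p=4, seed=6)
        res = fit_era(y, X, two_block_spec)
        assert 0.0 <= res.fit <= 1.0

    def test_sign_convention_first_weight_positive(self, make_data):
        bs = BlockSpec([("a", (0, 1)), ("b", (2, 3))])
        spec = ModelSpec(bs, [Term("linear", "a"), Term("linear", "b")])
        for seed in range(8):
            X, y = make_data(n=50, p=4, seed=seed, coef=np.array([-0.5, -0.3, 0.4, 0.2]))
            res = fit_era(y, X, spec)
            for w in res.params.weights.values():
                nz = w[np.abs(w) > 1e-12]
                assert nz[0] > 0

    def test_sign_flip_leaves_predictions_unchanged(self, make_data):
        # flipping a block's weights and its coefficient is a symmetry;
        # reported solution must reproduce the fitted values regardless
        X, y = make_data(n=50, p=4, seed=9, coef=np.array([-0.5, -0.4, 0.1, 0.2]))
        bs = BlockSpec([("a", (0, 1)), ("b", (2, 3))])
        spec = ModelSpec(bs, [Term("linear", "a"), Term("linear", "b")])
        res = fit_era(y, X, spec)
        assert rmse(y, predict(res, X)) == pytest.approx(res.rmse_train, abs=1e-10)

    def test_warm_started_nesting_gives_monotone_fit(self, make_data):
        from eracv.simulation import candidate_specs, generate_dataset, make_truth

        truth = make_truth(2, seed=21)
        X, y = generate_dataset(truth.sigma, 80, seed=22)
        specs = candidate_specs(truth.block_spec())
        fits = {}
        prev = None
        for name in ("f0", "f1", "f2", "f3"):
            fits[name] = fit_era(y, X, specs[name], init_params=prev)
            prev = fits[name].params
        values = [fits[n].fit for n in ("f0", "f1", "f2", "f3")]
        assert values == sorted(values)

    def test_parameter_recovery_at_large_n(self):
        from eracv.simulation import candidate_specs, generate_dataset, make_truth

        truth = make_truth(2, seed=31)
        X, y = generate_dataset(truth.sigma, 1000, seed=32)
        spec = candidate_specs(truth.block_spec())["f1"]
        res = fit_era(y, X, spec)
        np.testing.assert_allclose(res.params.b, truth.b, atol=0.05)
        for w_hat, w_true in zip(res.params.weights.values(), truth.weights):
            assert min(
                np.abs(w_hat - w_true).max(), np.abs(w_hat + w_true).max()
            ) < 0.1

    def test_insufficient_data_raises(self, two_block_spec):
        X = np.random.default_rng(0).standard_normal((3, 4))
        with pytest.raises(InsufficientDataError):
            fit_era(np.arange(3.0), X, two_block_spec)

    def test_constant_response_raises(self, two_block_spec, make_data):
        X, _ = make_data(n=20, p=4)
        with pytest.raises(DegenerateResponseError):
            fit_era(np.full(20, 3.0), X, two_block_spec)

    def test_rank_deficient_block_warns_but_fits(self):
        rng = np.random.default_rng(7)
        x0 = rng.standard_normal(30)
        X = np.column_stack([x0, 2.0 * x0, rng.standard_normal(30)])
        y = x0 + rng.standard_normal(30)
        bs = BlockSpec([("a", (0, 1)), ("b", (2,))])
        spec = ModelSpec(bs, [Term("linear", "a"), Term("linear", "b")])
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            res = fit_era(y, X, spec)
        assert np.isfinite(res.phi)

    def test_random_init_reproducible_under_seed(self, two_block_spec, make_data):
        X, y = make_data(n=40, p=4, seed=8)
        opts = FitOptions(init="random", seed=123)
        r1 = fit_era(y, X, two_block_spec, opts)
        r2 = fit_era(y, X, two_block_spec, opts)
        assert r1.phi == r2.phi
        np.testing.assert_array_equal(r1.params.b, r2.params.b)


class TestPredict:
    def test_training_data_reproduces_fitted_values(self, two_block_spec, make_data):
        X, y = make_data(n=40, p=4, seed=10)
        res = fit_era(y, X, two_block_spec)
        y_hat = predict(res, X)
        np.testing.assert_allclose(
            y_hat, res.term_scores @ res.params.b + y.mean(), atol=1e-10
        )

    def test_row_at_training_means_predicts_response_mean(self, two_block_spec, make_data):
        X, y = make_data(n=40, p=4, seed=12)
        res = fit_era(y, X, two_block_spec)
        y_hat = predict(res, X.mean(axis=0)[None, :])
        assert y_hat[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_single_block_hand_prediction(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        bs = BlockSpec([("a", (0,))])
        spec = ModelSpec(bs, [Term("linear", "a")])
        res = fit_era(y, X, spec)
        x_new = np.array([[2.5]])
        z = (2.5 - X.mean()) / X.std()
        expected = y.mean() + res.params.b[0] * res.params.weights["a"][0] * z
        assert predict(res, x_new)[0] == pytest.approx(expected, abs=1e-10)
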