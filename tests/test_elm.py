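import numpy as np
import pytest

from ppielm import (decision_scores, fit, init_hidden_layer, load_model,
                    predict, save_model, solve_output_weights)
from ppielm.elm import (ACTIVATIONS, MinMaxScaler, auto_hidden_count,
                        hidden_output)


class TestInit:
    def test_same_seed_identical_weights(self):
        a = init_hidden_layer(10, 5, seed=3)
        b = init_hidden_layer(10, 5, seed=3)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.array_equal(a.biases, b.biases)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            init_hidden_layer(10, 0)
        with pytest.raises(ValueError, match="activation"):
            init_hidden_layer(10, 5, activation="relu")

    def test_weights_are_centered_uniform(self):
        model = init_hidden_layer(1000, 100, seed=0)
        draws = np.concatenate([model.input_weights.ravel(), model.biases])
        # uniform[-1,1]: mean 0, se = 1/sqrt(3 n)
        se = 1 / np.sqrt(3 * draws.size)
        assert abs(draws.mean()) < 3 * se
        assert draws.min() >= -1 and draws.max() <= 1


class TestHiddenOutput:
    def test_sigmoid_at_zero_is_half(self):
        model = init_hidden_layer(3, 4, seed=0)
        model.input_weights[:] = 0
        model.biases[:] = 0
        H = hidden_output(model, np.ones((5, 3)))
        assert H == pytest.approx(np.full((5, 4), 0.5))

    def test_hardlim_is_binary(self, rng):
        model = init_hidden_layer(3, 4, activation="hardlim", seed=1)
        H = hidden_output(model, rng.normal(size=(10, 3)))
        assert set(np.unique(H)) <= {0.0, 1.0}

    def test_matches_scalar_loop(self, rng):
        model = init_hidden_layer(3, 5, seed=2)
        X = rng.normal(size=(5, 3))
        H = hidden_output(model, X)
        for j in range(5):
            for i in range(5):
                z = float(model.input_weights[i] @ X[j] + model.biases[i])
                assert H[j, i] == pytest.approx(1 / (1 + np.exp(-z)))

    def test_feature_mismatch(self, rng):
        model = init_hidden_layer(3, 4)
        with pytest.raises(ValueError, match="mismatch"):
            hidden_output(model, rng.normal(size=(5, 7)))

    @pytest.mark.parametrize("name", sorted(ACTIVATIONS))
    def test_activation_ranges(self, rng, name):
        z = rng.normal(scale=3, size=1000)
        out = ACTIVATIONS[name](z)
        assert np.all(np.isfinite(out))
        if name in ("sigmoid", "hardlim", "gaussian", "tribas"):
            assert out.min() >= 0 and out.max() <= 1


class TestSolve:
    def test_square_invertible_exact(self, rng):
        H = rng.normal(size=(6, 6)) + 6 * np.eye(6)
        T = rng.normal(size=(6, 1))
        beta = solve_output_weights(H, T)
        assert H @ beta == pytest.approx(T, abs=1e-8)

    def test_matches_independent_least_squares(self, rng):
        for _ in range(5):
            H = rng.normal(size=(50, 10))
            T = rng.normal(size=(50, 1))
            beta = solve_output_weights(H, T)
            oracle = np.linalg.pinv(H) @ T
            assert beta == pytest.approx(oracle, abs=1e-8)

    def test_minimum_norm_among_minimizers(self, rng):
        # rank-deficient: duplicate columns
        A = rng.normal(size=(20, 3))
        H = np.hstack([A, A])
        T = rng.normal(size=(20, 1))
        beta = solve_output_weights(H, T)
        pinv_beta = np.linalg.pinv(H) @ T
        assert beta == pytest.approx(pinv_beta, abs=1e-8)

    def test_nonfinite_rejected(self):
        H = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            solve_output_weights(H, np.array([[1.0]]))

    def test_residual_optimality_under_perturbation(self, rng):
        H = rng.normal(size=(30, 8))
        T = rng.normal(size=(30, 1))
        beta = solve_output_weights(H, T)
        base = np.linalg.norm(H @ beta - T)
        for _ in range(20):
            delta = rng.normal(scale=0.1, size=beta.shape)
            assert np.linalg.norm(H @ (beta + delta) - T) >= base - 1e-10


class TestFit:
    def test_auto_hidden_count_is_nine_percent(self):
        assert auto_hidden_count(1000) == 90
        assert auto_hidden_count(5) == 1  # floor of at least one neuron

    def test_fit_auto_on_1000_samples(self, rng):
        X = rng.normal(size=(1000, 5))
        y = (X[:, 0] > 0).astype(int)
        model = fit(X, y, L="auto", seed=0)
        assert model.L == 90

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit(X, np.ones(10))

    def test_determinism(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        m1 = fit(X, y, L=10, seed=5)
        m2 = fit(X, y, L=10, seed=5)
        assert np.array_equal(m1.output_weights, m2.output_weights)
        assert np.array_equal(decision_scores(m1, X), decision_scores(m2, X))

    def test_interpolation_with_L_equal_N(self, rng):
        # with as many hidden neurons as distinct samples, a sigmoid ELM
        # fits the training set exactly
        X = rng.normal(size=(20, 5))
        y = rng.integers(0, 2, size=20)
        y[0], y[1] = 0, 1  # both classes present
        model = fit(X, y, L=20, seed=0)
        assert np.array_equal(predict(model, X), y)
        scores = decision_scores(model, X)
        assert scores == pytest.approx(np.where(y == 1, 1.0, -1.0), abs=1e-6)

    def test_separable_blobs_high_accuracy(self, rng):
        n = 200
        X = np.vstack([rng.normal(loc=-2, size=(n, 2)),
                       rng.normal(loc=2, size=(n, 2))])
        y = np.repeat([0, 1], n)
        model = fit(X, y, L=20, seed=1)
        acc = (predict(model, X) == y).mean()
        assert acc >= 0.99

    def test_training_accuracy_nondecreasing_in_L(self, rng):
        X = rng.normal(size=(100, 4))
        y = (np.sin(X[:, 0] * 2) + X[:, 1] > 0).astype(int)
        accs = []
        for L in (2, 5, 10, 25, 50, 100):
            model = fit(X, y, L=L, seed=7)
            accs.append((predict(model, X) == y).mean())
        # allow small ties/noise from the random hidden layer
        for lo, hi in zip(accs, accs[1:]):
            assert hi >= lo - 0.03

    def test_ridge_stabilizer_close_to_unregularized(self, rng):
        X = rng.normal(size=(50, 4))
        y = (X[:, 0] > 0).astype(int)
        m0 = fit(X, y, L=10, seed=2, ridge=0.0)
        m1 = fit(X, y, L=10, seed=2, ridge=1e-10)
        assert decision_scores(m1, X) == pytest.approx(
            decision_scores(m0, X), abs=1e-4)


class TestScoresAndPersistence:
    def test_threshold_matches_predict(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit(X, y, L=8, seed=0)
        scores = decision_scores(model, X)
        assert np.array_equal(predict(model, X), (scores >= 0).astype(int))

    def test_unfitted_model_rejected(self, rng):
        model = init_hidden_layer(3, 4)
        with pytest.raises(ValueError, match="not fitted"):
            decision_scores(model, rng.normal(size=(2, 3)))

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit(X, y, L=6, seed=0)
        perm = rng.permutation(30)
        assert np.array_equal(decision_scores(model, X)[perm],
                              decision_scores(model, X[perm]))

    def test_serialization_round_trip_bit_exact(self, rng, tmp_path):
        X = rng.normal(size=(50, 6))
        y = (X[:, 0] - X[:, 2] > 0).astype(int)
        model = fit(X, y, L=12, activation="gaussian", seed=9, ridge=1e-6)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.activation == "gaussian"
        assert back.L == 12
        assert np.array_equal(decision_scores(back, X),
                              decision_scores(model, X))


def test_scaler_maps_training_data_to_unit_interval(rng):
    X = rng.normal(size=(30, 5)) * 10 + 3
    X[:, 2] = 7.0  # constant feature
    scaler = MinMaxScaler.fit(X)
    Z = scaler.transform(X)
    assert Z.min() >= 0 and Z.max() <= 1
    assert np.all(Z[:, 2] == 0)
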