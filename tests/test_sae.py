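"""Sparse autoencoder: costs, gradients, training, stacking, grid search."""

import dataclasses

import numpy as np
import pytest

from tugsae import (
    AutoencoderLayer,
    SAEHyperparams,
    TrainConfig,
    ae_cost,
    build_and_train_sae,
    decode,
    encode,
    grid_search,
    l2_penalty,
    mean_activation,
    sparsity_penalty,
    train_autoencoder,
)
from tugsae.sae import _ae_cost_grad, _init_layer, _pack


def _random_layer(rng, d_in=6, d_hidden=4, lam=0.01, beta=3.0, rho=0.05):
    return AutoencoderLayer(
        W1=rng.normal(0, 0.5, (d_hidden, d_in)),
        b1=rng.normal(0, 0.1, d_hidden),
        W2=rng.normal(0, 0.5, (d_in, d_hidden)),
        b2=rng.normal(0, 0.1, d_in),
        lambda_=lam,
        beta=beta,
        rho=rho,
    )


class TestEncodeDecode:
    def test_zero_weights_give_half_activation(self):
        layer = AutoencoderLayer(
            W1=np.zeros((4, 6)), b1=np.zeros(4), W2=np.zeros((6, 4)), b2=np.zeros(6)
        )
        assert np.allclose(encode(layer, np.ones(6)), 0.5)
        assert np.allclose(decode(layer, np.ones(4)), 0.5)

    def test_round_trip_preserves_length(self, rng):
        layer = _random_layer(rng)
        x = rng.uniform(size=6)
        assert decode(layer, encode(layer, x)).shape == x.shape

    def test_matches_matrix_multiply_oracle(self, rng):
        layer = _random_layer(rng)
        x = rng.uniform(size=6)
        expected = 1 / (1 + np.exp(-(layer.W1 @ x + layer.b1)))
        assert np.allclose(encode(layer, x), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        layer = _random_layer(rng)
        with pytest.raises(ValueError):
            encode(layer, np.ones(7))


class TestMeanActivation:
    def test_single_example_equals_its_code(self, rng):
        layer = _random_layer(rng)
        x = rng.uniform(size=6)
        assert np.allclose(mean_activation(layer, x), encode(layer, x))

    def test_matches_loop_oracle(self, rng):
        layer = _random_layer(rng)
        X = rng.uniform(size=(7, 6))
        looped = sum(encode(layer, x) for x in X) / len(X)
        assert np.allclose(mean_activation(layer, X), looped, atol=1e-14)

    def test_empty_input_rejected(self, rng):
        layer = _random_layer(rng)
        with pytest.raises(ValueError):
            mean_activation(layer, np.empty((0, 6)))


class TestSparsityPenalty:
    def test_zero_at_target(self):
        assert sparsity_penalty(np.full(5, 0.05), 0.05) == pytest.approx(0.0, abs=1e-14)

    def test_scalar_oracle(self):
        # Direct evaluation: rho log(rho/p) + (1-rho) log((1-rho)/(1-p)).
        expected = 0.5 * np.log(0.5 / 0.25) + 0.5 * np.log(0.5 / 0.75)
        assert sparsity_penalty(np.array([0.25]), 0.5) == pytest.approx(expected, abs=1e-14)

    def test_nonnegative_and_convex_around_target(self):
        rho, h = 0.2, 1e-4
        f = lambda p: sparsity_penalty(np.array([p]), rho)
        assert f(0.3) > 0 and f(0.1) > 0
        second_diff = f(rho + h) - 2 * f(rho) + f(rho - h)
        assert second_diff > 0

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            sparsity_penalty(np.array([bad]), 0.5)


class TestL2Penalty:
    def test_zero_weights(self):
        assert l2_penalty([np.zeros((3, 3))]) == 0.0

    def test_single_weight(self):
        assert l2_penalty([np.array([[2.0]])]) == pytest.approx(2.0)

    def test_matches_loop_oracle(self, rng):
        mats = [rng.normal(size=(4, 5)), rng.normal(size=(5, 4))]
        looped = 0.5 * sum(w**2 for m in mats for w in m.ravel())
        assert l2_penalty(mats) == pytest.approx(looped, abs=1e-12)


class TestAeCost:
    def test_reduces_to_mse_without_regularization(self, rng):
        layer = _random_layer(rng, lam=0.0, beta=0.0)
        X = rng.uniform(size=(8, 6))
        cost, _ = ae_cost(layer, X)
        recon = decode(layer, encode(layer, X))
        assert cost == pytest.approx(np.sum((X - recon) ** 2) / 8, rel=1e-12)

    def test_cost_decomposition(self, rng):
        layer = _random_layer(rng, lam=0.7, beta=1.3, rho=0.1)
        X = rng.uniform(size=(8, 6))
        cost, _ = ae_cost(layer, X)
        recon = decode(layer, encode(layer, X))
        expected = (
            np.sum((X - recon) ** 2) / 8
            + 0.7 * l2_penalty([layer.W1, layer.W2])
            + 1.3 * sparsity_penalty(mean_activation(layer, X), 0.1)
        )
        assert cost == pytest.approx(expected, rel=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        # Central finite differences on a 6 x 4 x 6 toy layer.
        d_in, d_hidden = 6, 4
        X = rng.uniform(size=(5, d_in))
        theta = rng.normal(0, 0.5, size=2 * d_in * d_hidden + d_in + d_hidden)
        args = (X, d_in, d_hidden, 0.01, 3.0, 0.05)
        _, g = _ae_cost_grad(theta, *args)
        eps = 1e-6
        for i in rng.choice(len(theta), size=25, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (_ae_cost_grad(tp, *args)[0] - _ae_cost_grad(tm, *args)[0]) / (2 * eps)
            assert abs(num - g[i]) / max(1e-8, abs(num) + abs(g[i])) < 1e-6


class TestTrainAutoencoder:
    def test_training_reduces_cost(self, rng, fast_train_config):
        X = rng.uniform(size=(30, 12))
        layer = train_autoencoder(X, 5, 1e-4, 0.5, 0.1, fast_train_config)
        theta0 = _init_layer(12, 5, np.random.default_rng(fast_train_config.seed))
        initial, _ = _ae_cost_grad(theta0, X, 12, 5, 1e-4, 0.5, 0.1)
        final, _ = ae_cost(layer, X)
        assert final < initial

    def test_identical_seeds_identical_weights(self, rng, fast_train_config):
        X = rng.uniform(size=(20, 10))
        a = train_autoencoder(X, 4, 0.0, 0.0, 0.1, fast_train_config)
        b = train_autoencoder(X, 4, 0.0, 0.0, 0.1, fast_train_config)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_rank_one_data_is_well_reconstructed_by_one_neuron(self, rng):
        # Rank-1 input set: a single hidden unit should reconstruct far
        # better than the data variance. Oracle is the data's own spread.
        u = rng.uniform(0.2, 0.8, size=10)
        c = rng.uniform(size=40)
        X = 0.5 + 0.4 * np.outer(c - 0.5, u)
        cfg = TrainConfig(max_iterations=300, supervised_iterations=10, seed=2)
        layer = train_autoencoder(X, 1, 0.0, 0.0, 0.5, cfg)
        mse = np.mean((X - decode(layer, encode(layer, X))) ** 2)
        var = np.mean((X - X.mean(axis=0)) ** 2)
        assert mse < 0.1 * var

    def test_strong_l2_shrinks_weights(self, rng, fast_train_config):
        X = rng.uniform(size=(20, 8))
        free = train_autoencoder(X, 4, 0.0, 0.0, 0.1, fast_train_config)
        shrunk = train_autoencoder(X, 4, 100.0, 0.0, 0.1, fast_train_config)
        assert np.abs(shrunk.W1).mean() < np.abs(free.W1).mean()


class TestSparsityEffect:
    def test_beta_pulls_mean_activation_toward_target(self, rng):
        # Increasing beta from 0 to 4 shrinks |rho_hat - rho| on average.
        rho = 0.05
        devs = {0.0: [], 4.0: []}
        for seed in range(5):
            X = np.random.default_rng(seed).uniform(size=(25, 16))
            for beta in devs:
                cfg = TrainConfig(max_iterations=60, supervised_iterations=10, seed=seed)
                layer = train_autoencoder(X, 8, 0.0, beta, rho, cfg)
                devs[beta].append(np.abs(mean_activation(layer, X) - rho).mean())
        assert np.mean(devs[4.0]) < np.mean(devs[0.0])


class TestStackedClassifier:
    def _toy_images(self, rng, n=16, d=24):
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = rng.uniform(0.1, 0.3, size=(n, d))
        X[y == 1, : d // 2] += 0.5  # linearly separable pattern
        return np.clip(X, 0, 1), y

    def test_separable_images_reach_perfect_training_accuracy(self, rng, fast_train_config):
        X, y = self._toy_images(rng)
        clf = build_and_train_sae(
            X, y, SAEHyperparams(n1=10, n2=4), fast_train_config
        )
        assert (clf.predict(X) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self, rng, fast_train_config):
        X, y = self._toy_images(rng)
        clf = build_and_train_sae(X, y, SAEHyperparams(n1=10, n2=4), fast_train_config)
        P = clf.predict_proba(rng.uniform(size=(100, 24)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_supervised_loss_is_recorded_and_descends_on_average(self, rng, fast_train_config):
        X, y = self._toy_images(rng)
        clf = build_and_train_sae(X, y, SAEHyperparams(n1=10, n2=4), fast_train_config)
        trace = clf.supervised_loss_
        assert len(trace) >= 2
        assert trace[-1] <= trace[0]

    def test_degenerate_labels_rejected(self, rng, fast_train_config):
        X, _ = self._toy_images(rng)
        with pytest.raises(ValueError):
            build_and_train_sae(X, np.ones(len(X), int), SAEHyperparams(10, 4), fast_train_config)

    def test_seeded_fit_is_deterministic(self, rng, fast_train_config):
        X, y = self._toy_images(rng)
        h = SAEHyperparams(n1=10, n2=4)
        a = build_and_train_sae(X, y, h, fast_train_config)
        b = build_and_train_sae(X, y, h, fast_train_config)
        assert np.array_equal(a.encoder1.W1, b.encoder1.W1)
        assert np.array_equal(a.softmax_W, b.softmax_W)


class TestGridSearch:
    def test_table_shape_and_argmin_contract(self, rng):
        X = rng.uniform(size=(12, 20))
        cfg = TrainConfig(max_iterations=10, supervised_iterations=5, optimizer="CG", seed=9)
        res = grid_search(X, n1_values=(4, 8), n2_values=(2, 3), runs=2, config=cfg)
        assert res.mse_table.shape == (2, 2)
        i = res.n1_values.index(res.best_pair[0])
        j = res.n2_values.index(res.best_pair[1])
        assert res.mse_table[i, j] == res.mse_table.min()

    def test_reproducible_under_master_seed(self, rng):
        X = rng.uniform(size=(10, 15))
        cfg = TrainConfig(max_iterations=8, supervised_iterations=5, optimizer="CG", seed=4)
        a = grid_search(X, n1_values=(3, 5), n2_values=(2,), runs=2, config=cfg)
        b = grid_search(X, n1_values=(3, 5), n2_values=(2,), runs=2, config=cfg)
        assert np.array_equal(a.mse_table, b.mse_table)
        assert a.best_pair == b.best_pair
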