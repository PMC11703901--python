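import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swarmnet as sn
from swarmnet.ann import (
    MLPConfig,
    ParameterError,
    TrainedMLP,
    _init_weights,
    mse_loss_gradients,
    split_indices,
)


def uniform_xy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    return x[:, None], x.copy(), rng


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": -0.1},
            {"n_hidden": 0},
            {"mccv_iterations": 0},
            {"train_fraction": 0.7},  # sums to 1.1
            {"train_fraction": 0.0, "val_fraction": 0.8},
            {"mse_improvement_threshold": 0.0},
            {"seed": -1},
            {"init_weight_range": (1.0, -1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MLPConfig(**kwargs)

    def test_defaults_reflect_training_protocol(self):
        c = MLPConfig()
        assert (c.learning_rate, c.momentum) == (0.1, 0.5)
        assert c.init_weight_range == (-1.0, 1.0)
        assert (c.max_epochs, c.patience_epochs) == (3000, 1000)
        assert (c.train_fraction, c.val_fraction, c.test_fraction) == (0.6, 0.2, 0.2)
        assert c.mccv_iterations == 50


class TestTrainMLP:
    def test_learns_identity_map(self):
        X, y, _ = uniform_xy()
        mlp = sn.train_mlp(X, y, MLPConfig(), split_seed=1, init_seed=2)
        assert mlp.val_mse < 0.01
        assert mlp.val_pearson_r > 0.95

    def test_null_target_low_correlation(self):
        X, _, rng = uniform_xy()
        hits = 0
        for seed in range(10):
            y = np.random.default_rng(1000 + seed).uniform(0, 1, 200)
            mlp = sn.train_mlp(X, y, MLPConfig(max_epochs=300, patience_epochs=100),
                               split_seed=seed, init_seed=seed)
            hits += abs(mlp.val_pearson_r) < 0.7
        assert hits >= 9

    def test_bit_identical_given_seeds(self):
        X, y, _ = uniform_xy()
        cfg = MLPConfig(max_epochs=200, patience_epochs=50)
        a = sn.train_mlp(X, y, cfg, split_seed=3, init_seed=4)
        b = sn.train_mlp(X, y, cfg, split_seed=3, init_seed=4)
        assert np.array_equal(a.W_in_hidden, b.W_in_hidden)
        assert np.array_equal(a.b_hidden, b.b_hidden)
        assert a.b_out == b.b_out and a.epochs_run == b.epochs_run

    def test_early_stopping_bounds(self):
        X, y, _ = uniform_xy()
        cfg = MLPConfig(max_epochs=50, patience_epochs=50)
        mlp = sn.train_mlp(X, y, cfg, split_seed=1, init_seed=1)
        assert mlp.epochs_run <= 50
        # patience == max_epochs: the patience rule can never fire
        assert mlp.stop_reason == "max_epochs"

    def test_mse_target_stop(self):
        X, y, _ = uniform_xy()
        cfg = MLPConfig(max_epochs=3000, patience_epochs=1000, mse_target=0.5)
        mlp = sn.train_mlp(X, y, cfg, split_seed=1, init_seed=1)
        assert mlp.stop_reason == "threshold"
        assert mlp.epochs_run < 50

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            sn.train_mlp(np.ones((5, 1)) * 0.5, np.ones(5) * 0.5, MLPConfig(),
                         split_seed=0, init_seed=0)

    def test_serialization_roundtrip(self):
        X, y, _ = uniform_xy(50, 3)
        mlp = sn.train_mlp(X, y, MLPConfig(max_epochs=20, patience_epochs=20),
                           split_seed=1, init_seed=1)
        back = TrainedMLP.from_json(mlp.to_json())
        assert np.array_equal(back.W_in_hidden, mlp.W_in_hidden)
        assert back.stop_reason == mlp.stop_reason
        assert back.val_pearson_r == mlp.val_pearson_r


class TestSeedIsolation:
    def test_split_seed_changes_partitions_only(self):
        cfg = MLPConfig()
        tr1, va1, te1 = split_indices(100, cfg, 1)
        tr2, _, _ = split_indices(100, cfg, 2)
        assert not np.array_equal(tr1, tr2)
        assert len(tr1) == 60 and len(va1) == 20 and len(te1) == 20
        w1 = _init_weights(cfg, 5, 7)
        w2 = _init_weights(cfg, 5, 7)
        assert all(np.array_equal(a, b) for a, b in zip(w1[:3], w2[:3]))

    def test_init_seed_changes_weights_only(self):
        cfg = MLPConfig()
        w1 = _init_weights(cfg, 5, 7)
        w2 = _init_weights(cfg, 5, 8)
        assert not np.array_equal(w1[0], w2[0])
        tr1, _, _ = split_indices(100, cfg, 3)
        tr2, _, _ = split_indices(100, cfg, 3)
        assert np.array_equal(tr1, tr2)


class TestPredict:
    def zero_net(self, n_in=3, h=2):
        return TrainedMLP(
            input_gene_ids=tuple(f"g{i}" for i in range(n_in)),
            W_in_hidden=np.zeros((n_in, h)), b_hidden=np.zeros(h),
            W_hidden_out=np.zeros(h), b_out=0.0,
            epochs_run=0, stop_reason="max_epochs",
            train_mse=0.0, val_mse=0.0, val_pearson_r=0.0,
        )

    def test_zero_weights_give_half(self):
        mlp = self.zero_net()
        X = np.random.default_rng(0).uniform(0, 1, (10, 3))
        assert np.allclose(sn.predict(mlp, X), 0.5)

    def test_matches_manual_forward_pass(self):
        rng = np.random.default_rng(5)
        mlp = self.zero_net(2, 2)
        mlp.W_in_hidden = rng.normal(0, 1, (2, 2))
        mlp.b_hidden = rng.normal(0, 1, 2)
        mlp.W_hidden_out = rng.normal(0, 1, 2)
        mlp.b_out = float(rng.normal())
        X = rng.uniform(0, 1, (6, 2))
        # independent spreadsheet-style evaluation, scalar by scalar
        expected = []
        for row in X:
            hs = []
            for j in range(2):
                z = mlp.b_hidden[j] + row[0] * mlp.W_in_hidden[0, j] \
                    + row[1] * mlp.W_in_hidden[1, j]
                hs.append(1 / (1 + np.exp(-z)))
            z2 = mlp.b_out + hs[0] * mlp.W_hidden_out[0] + hs[1] * mlp.W_hidden_out[1]
            expected.append(1 / (1 + np.exp(-z2)))
        assert np.allclose(sn.predict(mlp, X), expected, atol=1e-12, rtol=0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            sn.predict(self.zero_net(3), np.ones((4, 2)))


class TestMCCV:
    def test_copy_candidate_beats_null(self):
        X, y, rng = uniform_xy()
        cfg = MLPConfig(mccv_iterations=10, max_epochs=200, patience_epochs=50, seed=5)
        copy_score = sn.mccv_mse(X, y, cfg)
        null_score = sn.mccv_mse(rng.uniform(0, 1, (200, 1)), y, cfg)
        assert copy_score < 0.02
        assert copy_score < null_score
        # null score is near the variance of y on the unit interval
        assert null_score == pytest.approx(np.var(y), rel=0.5)

    def test_single_iteration_is_one_split(self):
        X, y, _ = uniform_xy(100, 2)
        cfg = MLPConfig(mccv_iterations=1, max_epochs=100, patience_epochs=50, seed=9)
        a = sn.mccv_mse(X, y, cfg)
        b = sn.mccv_mse(X, y, cfg)
        assert a == b  # deterministic degenerate case

    def test_requires_test_partition(self):
        X, y, _ = uniform_xy(100, 2)
        cfg = MLPConfig(train_fraction=0.8, val_fraction=0.2, test_fraction=0.0)
        with pytest.raises(ParameterError):
            sn.mccv_mse(X, y, cfg)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_backprop_gradient_matches_finite_differences(seed):
    """Analytic gradients of the MSE loss agree with central differences."""
    rng = np.random.default_rng(seed)
    n_in = int(rng.integers(1, 6))
    h = int(rng.integers(1, 4))
    W1 = rng.normal(0, 1, (n_in, h))
    b1 = rng.normal(0, 1, h)
    W2 = rng.normal(0, 1, h)
    b2 = float(rng.normal())
    X = rng.uniform(0, 1, (15, n_in))
    y = rng.uniform(0, 1, 15)

    def loss(W1=W1, b1=b1, W2=W2, b2=b2):
        hid = 1 / (1 + np.exp(-(X @ W1 + b1)))
        o = 1 / (1 + np.exp(-(hid @ W2 + b2)))
        return np.mean((o - y) ** 2)

    _, g = mse_loss_gradients(W1, b1, W2, b2, X, y)
    eps = 1e-6
    i, j = int(rng.integers(0, n_in)), int(rng.integers(0, h))
    Wp, Wm = W1.copy(), W1.copy()
    Wp[i, j] += eps
    Wm[i, j] -= eps
    fd = (loss(W1=Wp) - loss(W1=Wm)) / (2 * eps)
    an = g["W1"][i, j]
    assert abs(fd - an) <= 1e-5 * max(1e-6, abs(fd) + abs(an))
    bp = b2 + eps
    bm = b2 - eps
    fd2 = (loss(b2=bp) - loss(b2=bm)) / (2 * eps)
    assert abs(fd2 - g["b2"]) <= 1e-5 * max(1e-6, abs(fd2) + abs(g["b2"]))
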