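"""LSTM cell fidelity against a scalar-loop oracle, softmax properties,
sequence conversion, training behaviour, and optimizer/regularizer checks."""

import math

import numpy as np
import pytest

from ecgwolf.errors import TrainingError
from ecgwolf.features import FeatureMatrix
from ecgwolf.gwo import FeatureMask
from ecgwolf.lstm import (Adam, LSTMParams, LSTMState, TrainConfig,
                          evaluate_loss, init_params, lstm_cell_step, predict,
                          softmax, to_sequences, train)


def _zero_params(input_size=3, hidden=4, classes=5):
    HD = hidden + input_size
    return LSTMParams(
        W_i=np.zeros((hidden, HD)), W_f=np.zeros((hidden, HD)),
        W_c=np.zeros((hidden, HD)), W_o=np.zeros((hidden, HD)),
        b_i=np.zeros(hidden), b_f=np.zeros(hidden),
        b_c=np.zeros(hidden), b_o=np.zeros(hidden),
        W_out=np.zeros((classes, hidden)), b_out=np.zeros(classes),
    )


def _scalar_cell_oracle(x, h0, c0, p):
    """Evaluate the gate equations element by element in pure Python."""
    H = p.hidden_size
    z = list(h0) + list(x)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_new, c_new = [], []
    for k in range(H):
        i = sig(sum(p.W_i[k][j] * z[j] for j in range(len(z))) + p.b_i[k])
        f = sig(sum(p.W_f[k][j] * z[j] for j in range(len(z))) + p.b_f[k])
        g = math.tanh(sum(p.W_c[k][j] * z[j] for j in range(len(z))) + p.b_c[k])
        c = f * c0[k] + i * g
        o = sig(sum(p.W_o[k][j] * z[j] for j in range(len(z))) + p.b_o[k])
        h_new.append(o * math.tanh(c))
        c_new.append(c)
    return np.array(h_new), np.array(c_new)


class TestCellStep:
    def test_all_zero_parameters_give_zero_state(self):
        p = _zero_params()
        st = lstm_cell_step(np.zeros(3), LSTMState(np.zeros(4), np.zeros(4)), p)
        assert np.array_equal(st.h, np.zeros(4))
        assert np.array_equal(st.c, np.zeros(4))

    def test_matches_scalar_oracle_on_random_draws(self, rng):
        for _ in range(100):
            p = init_params(4, 3, 5, rng)
            x = rng.normal(size=4)
            h0 = rng.normal(size=3)
            c0 = rng.normal(size=3)
            st = lstm_cell_step(x, LSTMState(h0.copy(), c0.copy()), p)
            h_ref, c_ref = _scalar_cell_oracle(x, h0, c0, p)
            assert np.max(np.abs(st.h - h_ref)) <= 1e-8
            assert np.max(np.abs(st.c - c_ref)) <= 1e-8

    def test_gate_outputs_bounded(self, rng):
        p = init_params(6, 5, 5, rng)
        st = lstm_cell_step(rng.normal(size=6),
                            LSTMState(np.zeros(5), np.zeros(5)), p)
        assert np.all(np.abs(st.h) < 1.0)  # |o * tanh(c)| < 1

    def test_shape_mismatch_rejected(self, rng):
        p = init_params(4, 3, 5, rng)
        with pytest.raises(ValueError):
            lstm_cell_step(rng.normal(size=5),
                           LSTMState(np.zeros(3), np.zeros(3)), p)


class TestSoftmax:
    def test_equal_logits_give_uniform(self):
        assert np.allclose(softmax(np.zeros(5)), 0.2)

    def test_shift_invariance(self, rng):
        o = rng.normal(size=7)
        assert np.allclose(softmax(o), softmax(o + 123.4), atol=1e-12)

    def test_sums_to_one_and_preserves_argmax(self, rng):
        for _ in range(50):
            o = rng.normal(scale=10, size=6)
            p = softmax(o)
            assert abs(p.sum() - 1.0) <= 1e-12
            assert p.argmax() == o.argmax()

    def test_extreme_logits_do_not_overflow(self):
        p = softmax(np.array([1e4, 0.0, -1e4]))
        assert np.all(np.isfinite(p)) and abs(p.sum() - 1.0) <= 1e-12


class TestToSequences:
    def _fm(self, rng, n=20, d=6):
        return FeatureMatrix(rng.normal(size=(n, d)),
                             [f"f{i}" for i in range(d)],
                             rng.integers(1, 6, size=n))

    def test_static_mode_shapes(self, rng):
        fm = self._fm(rng, n=100, d=20)
        bits = np.zeros(20, bool)
        bits[:12] = True
        X, y = to_sequences(fm, FeatureMask(bits))
        assert X.shape == (100, 1, 12)
        assert y.size == 100

    def test_identity_mask_preserves_rows(self, rng):
        fm = self._fm(rng)
        X, _ = to_sequences(fm, FeatureMask(np.ones(6, bool)))
        assert np.array_equal(X[:, 0, :], fm.values)

    def test_column_subset_matches_loop_oracle(self, rng):
        fm = self._fm(rng)
        bits = np.array([1, 0, 1, 0, 0, 1], bool)
        X, _ = to_sequences(fm, FeatureMask(bits))
        for r in range(fm.values.shape[0]):
            picked = [fm.values[r, j] for j in range(6) if bits[j]]
            assert np.array_equal(X[r, 0, :], picked)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            to_sequences(self._fm(rng), FeatureMask(np.zeros(6, bool)))


def _split(X, y, rng):
    order = rng.permutation(y.size)
    cut = int(0.8 * y.size)
    tr, va = order[:cut], order[cut:]
    return X[tr], y[tr], X[va], y[va]


@pytest.fixture(scope="module")
def trained(separable_clusters):
    X, y = separable_clusters
    seqs = X[:, None, :]
    rng = np.random.default_rng(0)
    Xtr, ytr, Xva, yva = _split(seqs, y, rng)
    cfg = TrainConfig(hidden_size=16, epochs=30, seed=0)
    model = train(Xtr, ytr, cfg, Xva, yva)
    return model, Xtr, ytr, Xva, yva


class TestTraining:
    def test_separable_clusters_learned(self, trained):
        model, Xtr, ytr, _, _ = trained
        pred, _ = predict(model, Xtr)
        assert np.mean(pred == ytr) >= 0.95

    def test_first_epoch_reduces_training_loss(self, trained, rng):
        model, Xtr, ytr, _, _ = trained
        class_labels = model.class_labels
        y_idx = np.searchsorted(class_labels, ytr)
        p0 = init_params(Xtr.shape[2], 16, class_labels.size,
                         np.random.default_rng(0))
        initial = evaluate_loss(Xtr, y_idx, p0, 0.001)
        assert model.training_history[0]["train_loss"] < initial

    def test_history_records_every_epoch(self, trained):
        model = trained[0]
        epochs = [h["epoch"] for h in model.training_history]
        assert epochs == list(range(len(epochs)))
        assert all("val_loss" in h and "val_acc" in h
                   for h in model.training_history)

    def test_same_seed_same_first_epoch_loss(self, separable_clusters):
        X, y = separable_clusters
        seqs = X[:, None, :]
        rng = np.random.default_rng(1)
        Xtr, ytr, Xva, yva = _split(seqs, y, rng)
        cfg = TrainConfig(hidden_size=8, epochs=2, seed=7)
        a = train(Xtr, ytr, cfg, Xva, yva)
        b = train(Xtr, ytr, cfg, Xva, yva)
        assert a.training_history[0]["batch_loss"] == \
               b.training_history[0]["batch_loss"]

    def test_early_stop_after_patience_checks(self, rng):
        # pure-noise task: validation loss stops improving almost at once
        X = rng.normal(size=(80, 1, 4))
        y = rng.integers(1, 3, size=80)
        Xv = rng.normal(size=(30, 1, 4))
        yv = rng.integers(1, 3, size=30)
        cfg = TrainConfig(hidden_size=4, epochs=200, seed=0,
                          early_stop_patience=3, dropout=0.0)
        model = train(X, y, cfg, Xv, yv)
        assert len(model.training_history) < 200
        vals = [h["val_loss"] for h in model.training_history]
        best_so_far = np.minimum.accumulate(vals)
        tail = vals[-3:]
        assert all(v >= best_so_far[-4] - 1e-12 for v in tail)

    def test_non_finite_loss_raises_training_error_with_epoch(self, rng):
        X = rng.normal(size=(40, 1, 3))
        X[0, 0, 0] = np.nan  # poisons the first batch's loss
        y = rng.integers(1, 3, size=40)
        cfg = TrainConfig(hidden_size=4, epochs=5, seed=0, dropout=0.0)
        with pytest.raises(TrainingError) as info:
            train(X, y, cfg, X[1:6], y[1:6])
        assert info.value.epoch == 0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(30, 1, 3))
        y = np.ones(30, int)
        with pytest.raises(ValueError):
            train(X, y, TrainConfig(), X[:5], y[:5])


class TestPredict:
    def test_probability_rows_sum_to_one(self, separable_clusters, rng):
        X, y = separable_clusters
        seqs = X[:50, None, :]
        cfg = TrainConfig(hidden_size=8, epochs=2, seed=0)
        model = train(seqs, y[:50], cfg, seqs[:10], y[:10])
        _, probs = predict(model, seqs)
        assert np.max(np.abs(probs.sum(axis=1) - 1.0)) <= 1e-9

    def test_repeat_calls_identical(self, separable_clusters):
        X, y = separable_clusters
        seqs = X[:50, None, :]
        cfg = TrainConfig(hidden_size=8, epochs=2, seed=0)
        model = train(seqs, y[:50], cfg, seqs[:10], y[:10])
        a = predict(model, seqs)
        b = predict(model, seqs)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])

    def test_dimension_mismatch_rejected(self, separable_clusters):
        X, y = separable_clusters
        seqs = X[:50, None, :]
        cfg = TrainConfig(hidden_size=8, epochs=1, seed=0)
        model = train(seqs, y[:50], cfg, seqs[:10], y[:10])
        with pytest.raises(ValueError):
            predict(model, seqs[:, :, :4])


class TestRegularization:
    def test_vanishing_learning_rate_leaves_weights_unchanged(self, rng):
        X = rng.normal(size=(30, 1, 3))
        y = rng.integers(1, 4, size=30)
        cfg = TrainConfig(hidden_size=4, epochs=3, seed=5,
                          learning_rate=1e-12, dropout=0.0)
        model = train(X, y, cfg, X[:5], y[:5])
        p0 = init_params(3, 4, 3, np.random.default_rng(5))
        for name, arr in model.params.arrays().items():
            assert np.max(np.abs(arr - p0.arrays()[name])) < 1e-6, name

    def test_pure_l2_objective_decays_weight_norm(self):
        # 2-unit toy driven by Adam on the L2 gradient alone
        rng = np.random.default_rng(3)
        p = init_params(2, 2, 2, rng)
        arrays = p.arrays()
        opt = Adam({n: a.shape for n, a in arrays.items()}, lr=0.001)
        l2 = 0.1
        norms = []
        for _ in range(50):
            grads = {n: l2 * a if n.startswith("W") else np.zeros_like(a)
                     for n, a in arrays.items()}
            opt.step(arrays, grads)
            norms.append(np.sqrt(sum(np.sum(a ** 2)
                                     for n, a in arrays.items()
                                     if n.startswith("W"))))
        assert all(b < a for a, b in zip(norms, norms[1:]))
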