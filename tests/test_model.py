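"""LSTM cell math, network architecture, training machinery."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcgvitals import nn
from bcgvitals.model import (
    BinCodec,
    LSTMParams,
    LSTMState,
    NetworkConfig,
    build_network,
    kfold_indices,
    lstm_cell_forward,
    reference_shape_trace,
    train,
    train_test_split_indices,
)


def _random_params(rng, d, h):
    return LSTMParams(
        W_f=rng.standard_normal((h, d)), W_i=rng.standard_normal((h, d)),
        W_o=rng.standard_normal((h, d)), W_c=rng.standard_normal((h, d)),
        U_f=rng.standard_normal((h, h)), U_i=rng.standard_normal((h, h)),
        U_o=rng.standard_normal((h, h)), U_c=rng.standard_normal((h, h)),
        b_f=rng.standard_normal(h), b_i=rng.standard_normal(h),
        b_o=rng.standard_normal(h), b_c=rng.standard_normal(h),
    )


def _scalar_reference_cell(x, state, p):
    """Independent per-component implementation of the gated recurrence."""
    h_dim = state.h.size
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))  # noqa: E731
    h_out = np.zeros(h_dim)
    c_out = np.zeros(h_dim)
    for j in range(h_dim):
        zf = sum(p.W_f[j, k] * x[k] for k in range(x.size))
        zf += sum(p.U_f[j, k] * state.h[k] for k in range(h_dim)) + p.b_f[j]
        zi = sum(p.W_i[j, k] * x[k] for k in range(x.size))
        zi += sum(p.U_i[j, k] * state.h[k] for k in range(h_dim)) + p.b_i[j]
        zo = sum(p.W_o[j, k] * x[k] for k in range(x.size))
        zo += sum(p.U_o[j, k] * state.h[k] for k in range(h_dim)) + p.b_o[j]
        zc = sum(p.W_c[j, k] * x[k] for k in range(x.size))
        zc += sum(p.U_c[j, k] * state.h[k] for k in range(h_dim)) + p.b_c[j]
        c_out[j] = sig(zf) * state.c[j] + sig(zi) * math.tanh(zc)
        h_out[j] = sig(zo) * math.tanh(c_out[j])
    return h_out, c_out


class TestLstmCell:
    def test_matches_independent_scalar_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = _random_params(rng, 3, 4)
            state = LSTMState(c=rng.standard_normal(4), h=np.tanh(rng.standard_normal(4)))
            x = rng.standard_normal(3)
            h, new = lstm_cell_forward(x, state, p)
            h_ref, c_ref = _scalar_reference_cell(x, state, p)
            assert np.max(np.abs(h - h_ref)) < 1e-10
            assert np.max(np.abs(new.c - c_ref)) < 1e-10

    def test_zero_weights_halve_the_cell_state(self):
        zeros = LSTMParams(*[np.zeros((2, 3))] * 4, *[np.zeros((2, 2))] * 4, *[np.zeros(2)] * 4)
        c_prev = np.array([0.8, -0.4])
        h, state = lstm_cell_forward(np.ones(3), LSTMState(c=c_prev, h=np.zeros(2)), zeros)
        np.testing.assert_allclose(state.c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_saturated_gates_preserve_memory(self):
        rng = np.random.default_rng(1)
        p = _random_params(rng, 3, 4)
        p.b_f[:] = 50.0   # forget gate ~1
        p.b_i[:] = -50.0  # input gate ~0
        c_prev = rng.standard_normal(4)
        _, state = lstm_cell_forward(rng.standard_normal(3),
                                     LSTMState(c=c_prev, h=np.zeros(4)), p)
        np.testing.assert_allclose(state.c, c_prev, atol=1e-10)

    def test_shape_mismatch_names_matrix(self):
        p = _random_params(np.random.default_rng(2), 3, 4)
        p.U_o = np.zeros((4, 5))
        with pytest.raises(ValueError, match="U_o"):
            lstm_cell_forward(np.zeros(3), LSTMState.zeros(4), p)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_gate_and_state_ranges(self, seed):
        rng = np.random.default_rng(seed)
        p = _random_params(rng, 2, 3)
        h, state = lstm_cell_forward(
            3 * rng.standard_normal(2),
            LSTMState(c=rng.standard_normal(3), h=np.tanh(rng.standard_normal(3))),
            p,
        )
        assert np.all(np.abs(h) < 1.0)
        assert np.all(np.isfinite(state.c))


class TestBinCodec:
    def test_round_trip_on_all_centres(self):
        codec = BinCodec(40.0, 151.0, 222)
        for k in range(222):
            assert codec.encode(codec.decode(k)) == k

    def test_lower_boundary_maps_to_bin_zero(self):
        assert BinCodec(40.0, 151.0, 222).encode(40.0) == 0

    def test_decode_error_bounded_by_half_bin_width(self):
        codec = BinCodec(40.0, 151.0, 222)
        for v in np.linspace(40.0, 151.0, 997):
            assert abs(codec.decode(codec.encode(v)) - v) <= codec.width / 2 + 1e-12

    def test_out_of_range_clamps_with_warning(self):
        codec = BinCodec(40.0, 151.0, 222)
        with pytest.warns(UserWarning):
            assert codec.encode(30.0) == 0
        with pytest.warns(UserWarning):
            assert codec.encode(200.0) == 221


class TestArchitecture:
    def test_shape_trace_reproduces_reference_table(self):
        assert build_network().shape_trace() == reference_shape_trace()

    def test_builds_are_deterministic_for_a_seed(self):
        a, b = build_network(), build_network()
        assert a.n_params() == b.n_params()
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_inconsistent_config_reports_first_bad_layer(self):
        with pytest.raises(ValueError, match="Conv1"):
            build_network(NetworkConfig(conv1_filters=16))

    def test_softmax_output_normalized(self):
        net = build_network()
        p = net.forward(np.random.default_rng(0).standard_normal((2, 6, 1, 56, 1)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def _tiny_config(**kw):
    base = dict(timesteps=3, feature_width=8, conv1_filters=2, conv2_filters=3,
                fc1_units=5, lstm1_units=4, lstm2_units=4, head="regression",
                n_outputs=1, dropout_rate=0.0, enforce_reference_shapes=False,
                lr=1e-2, epochs=30, batch_size=2, seed=1)
    base.update(kw)
    return NetworkConfig(**base)


class TestTraining:
    def test_loss_decreases_on_learnable_data(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 3, 1, 8, 1))
        y = X[:, :, 0, :2, 0].sum(axis=(1, 2)) * 3.0 + 50.0
        cfg = _tiny_config()
        net = build_network(cfg)
        net, history = train(net, X, y, cfg)
        first = np.mean(history["train_loss"][:3])
        last = np.mean(history["train_loss"][-3:])
        assert last < first

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 3, 1, 8, 1))
        y = X[:, 0, 0, 0, 0] * 2 + 60
        preds = []
        for _ in range(2):
            cfg = _tiny_config(epochs=5)
            net = build_network(cfg)
            net, _ = train(net, X, y, cfg)
            preds.append(net.predict(X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_untrained_model_refuses_to_predict(self):
        net = build_network(_tiny_config())
        with pytest.raises(RuntimeError):
            net.predict(np.zeros((1, 3, 1, 8, 1)))

    def test_empty_training_set_raises(self):
        cfg = _tiny_config()
        with pytest.raises(ValueError):
            train(build_network(cfg), np.zeros((0, 3, 1, 8, 1)), np.zeros(0), cfg)

    def test_softmax_head_trains_too(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((16, 3, 1, 8, 1))
        y = np.where(X[:, 0, 0, 0, 0] > 0, 70.0, 60.0)
        cfg = _tiny_config(head="softmax_bins", n_bins=30,
                           codec=dict(lo=55.0, hi=85.0, n_bins=30), epochs=20)
        net = build_network(cfg)
        net, history = train(net, X, y, cfg)
        assert history["train_loss"][-1] < history["train_loss"][0]
        pred = net.predict(X)
        assert np.all((pred >= 55.0) & (pred <= 85.0))


class TestSplits:
    def test_train_test_split_is_a_partition(self):
        tr, te = train_test_split_indices(50, 0.2, seed=0)
        assert te.size == 10
        assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(50))

    def test_kfold_covers_every_sample_once(self):
        folds = kfold_indices(37, k=10, seed=1)
        assert len(folds) == 10
        seen = np.concatenate([val for _, val in folds])
        assert np.array_equal(np.sort(seen), np.arange(37))
        for tr, val in folds:
            assert np.intersect1d(tr, val).size == 0


class TestDropout:
    def test_identity_at_eval_and_masking_at_train(self):
        layer = nn.Dropout(0.5, np.random.default_rng(0))
        x = np.ones((4, 10))
        np.testing.assert_array_equal(layer.forward(x, train=False), x)
        out = layer.forward(x, train=True)
        assert np.any(out == 0.0)
        assert np.all((out == 0.0) | (out == 2.0))
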