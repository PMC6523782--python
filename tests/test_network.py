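"""Forward-pass oracles, gradient checks and training-loop contracts.

Every forward stage is compared with an independently coded brute-force
reference written straight from the defining equations; the end-to-end
cross-entropy gradient is checked against central finite differences on a
miniature configuration.
"""

import numpy as np
import pytest

from lncsense import (
    EmbeddingTable,
    LstmCellParams,
    NetworkConfig,
    blstm_forward,
    conv_stage_forward,
    lstm_step,
    predict_proba,
)
from lncsense.network import (
    ClassifierModel,
    _lstm_forward_batch,
    conv_output_lengths,
    fit,
    init_model,
    loss_and_grads,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def random_cell(rng, D, H):
    g = lambda *s: rng.normal(0, 0.4, s)
    return LstmCellParams(
        W_i=g(H, D), W_g=g(H, D), W_f=g(H, D), W_o=g(H, D),
        U_i=g(H, H), U_g=g(H, H), U_f=g(H, H), U_o=g(H, H),
        b_i=g(H), b_g=g(H), b_f=g(H), b_o=g(H),
    )


def reference_lstm_step(x, h, c, p):
    """Oracle transcribed directly from the gate equations."""
    i = sigmoid(p.W_i @ x + p.U_i @ h + p.b_i)
    g = np.tanh(p.W_g @ x + p.U_g @ h + p.b_g)
    f = sigmoid(p.W_f @ x + p.U_f @ h + p.b_f)
    c_t = i * g + f * c
    o = sigmoid(p.W_o @ x + p.U_o @ h + p.b_o)
    return o * np.tanh(c_t), c_t


def reference_conv_stage(X, K, b, pool):
    """Triple-loop valid cross-correlation + ReLU + non-overlap max pool."""
    C_out, C_in, Kw = K.shape
    L = X.shape[1]
    L_c = L - Kw + 1
    conv = np.zeros((C_out, L_c))
    for co in range(C_out):
        for t in range(L_c):
            acc = b[co]
            for ci in range(C_in):
                for m in range(Kw):
                    acc += X[ci, t + m] * K[co, ci, m]
            conv[co, t] = max(acc, 0.0)
    L_p = L_c // pool
    out = np.zeros((C_out, L_p))
    for co in range(C_out):
        for t in range(L_p):
            out[co, t] = conv[co, t * pool : (t + 1) * pool].max()
    return out


def tiny_model(rng, **kw):
    defaults = dict(max_len=20, embedding_dim=3, lstm_hidden=3,
                    conv_filters=(4,), conv_kernels=(5,), pool_sizes=(2,), seed=0)
    defaults.update(kw)
    cfg = NetworkConfig(**defaults)
    V = 4
    E = np.zeros((V + 1, cfg.embedding_dim))
    E[1:] = rng.normal(0, 0.3, (V, cfg.embedding_dim))
    model = init_model(cfg, EmbeddingTable(E=E))
    for k in model.params:
        model.params[k] = model.params[k] + rng.normal(0, 0.05, model.params[k].shape)
    model.params["emb"][0] = 0
    return model, cfg, V


class TestLstmStep:
    def test_zero_weights_halve_cell_state(self, rng):
        H, D = 4, 3
        p = LstmCellParams(*[np.zeros((H, D))] * 4, *[np.zeros((H, H))] * 4, *[np.zeros(H)] * 4)
        c_prev = rng.normal(0, 1, H)
        h, c = lstm_step(rng.normal(0, 1, D), np.zeros(H), c_prev, p)
        np.testing.assert_allclose(c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_saturated_candidate_gate_limit(self, rng):
        H, D = 3, 2
        p = random_cell(rng, D, H)
        p.b_g[:] = 50.0  # g_t → 1
        x, h0 = rng.normal(0, 0.5, D), np.zeros(H)
        _, c = lstm_step(x, h0, np.zeros(H), p)
        i = sigmoid(p.W_i @ x + p.b_i)
        np.testing.assert_allclose(c, i, atol=1e-8)

    def test_matches_reference_on_random_instances(self, rng):
        """≥100 random cells vs the transcription oracle, agreement to 1e-12."""
        worst = 0.0
        for _ in range(100):
            D, H = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = random_cell(rng, D, H)
            x, h0, c0 = rng.normal(0, 1, D), rng.normal(0, 1, H), rng.normal(0, 1, H)
            h, c = lstm_step(x, h0, c0, p)
            h_ref, c_ref = reference_lstm_step(x, h0, c0, p)
            worst = max(worst, np.abs(h - h_ref).max(), np.abs(c - c_ref).max())
        assert worst < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        p = random_cell(rng, 3, 4)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(2), np.zeros(4), np.zeros(4), p)


class TestBatchedLstmAgainstStep:
    def test_batched_recurrence_equals_sequential_steps(self, rng):
        """The packed batched forward must replay lstm_step exactly."""
        D, H, T = 3, 4, 7
        Wx, Wh, b = rng.normal(0, 0.3, (D, 4 * H)), rng.normal(0, 0.3, (H, 4 * H)), rng.normal(0, 0.3, 4 * H)
        X = rng.normal(0, 1, (2, T, D))
        Hs, _ = _lstm_forward_batch(X, Wx, Wh, b)
        cell = LstmCellParams.from_packed(Wx, Wh, b)
        for bi in range(2):
            h, c = np.zeros(H), np.zeros(H)
            for t in range(T):
                h, c = lstm_step(X[bi, t], h, c, cell)
                np.testing.assert_allclose(Hs[bi, t], h, atol=1e-12)


class TestBlstmForward:
    def test_palindrome_with_tied_weights_is_time_symmetric(self, rng):
        model, cfg, V = tiny_model(rng, max_len=9)
        for name in ("Wx", "Wh", "b"):
            model.params[f"b_{name}"] = model.params[f"f_{name}"].copy()
        tokens = np.array([1, 2, 3, 4, 2, 4, 3, 2, 1])
        out = blstm_forward(tokens, model)  # (2H, L)
        H = cfg.lstm_hidden
        np.testing.assert_allclose(out[:H], out[H:, ::-1], atol=1e-12)

    def test_all_padding_input_driven_by_biases_only(self, rng):
        model, cfg, _ = tiny_model(rng)
        H = cfg.lstm_hidden
        out = blstm_forward(np.zeros(cfg.max_len, dtype=int), model)
        # first forward step from zero input and zero state: gates see biases only
        cell = model.lstm_cell("forward")
        h1, _ = lstm_step(np.zeros(cfg.embedding_dim), np.zeros(H), np.zeros(H), cell)
        np.testing.assert_allclose(out[:H, 0], h1, atol=1e-12)

    def test_single_token_sequence(self, rng):
        model, cfg, _ = tiny_model(rng, max_len=1, conv_kernels=(1,), pool_sizes=(1,))
        out = blstm_forward(np.array([2]), model)
        assert out.shape == (2 * cfg.lstm_hidden, 1)


class TestConvStage:
    def test_identity_kernel_recovers_input(self, rng):
        X = np.abs(rng.normal(1, 0.2, (1, 12)))
        K = np.zeros((1, 1, 3))
        K[0, 0, 0] = 1.0
        out = conv_stage_forward(X, K, np.zeros(1), pool=1)
        np.testing.assert_allclose(out[0], X[0, :10], atol=1e-15)

    def test_relu_floors_negative_preactivations(self, rng):
        X = rng.normal(0, 1, (2, 10))
        K = rng.normal(0, 0.1, (3, 2, 4))
        out = conv_stage_forward(X, K, np.full(3, -100.0), pool=2)
        assert (out == 0).all()

    def test_matches_triple_loop_oracle(self, rng):
        """≥100 random instances vs the brute-force conv+pool, to 1e-10."""
        worst = 0.0
        for _ in range(100):
            C_in, C_out = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            L = int(rng.integers(4, 16))
            Kw = int(rng.integers(1, min(5, L) + 1))
            pool = int(rng.integers(1, 4))
            if (L - Kw + 1) // pool < 1:
                pool = 1
            X = rng.normal(0, 1, (C_in, L))
            K = rng.normal(0, 1, (C_out, C_in, Kw))
            b = rng.normal(0, 1, C_out)
            got = conv_stage_forward(X, K, b, pool)
            ref = reference_conv_stage(X, K, b, pool)
            worst = max(worst, np.abs(got - ref).max())
        assert worst < 1e-10

    def test_kernel_longer_than_input_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter than kernel"):
            conv_stage_forward(np.zeros((1, 3)), np.zeros((1, 1, 5)), np.zeros(1), 1)

    def test_output_length_bookkeeping_full_architecture(self):
        """L=1000 through kernels 10/8/8 and pools 4/2/2 obeys the floor rule."""
        cfg = NetworkConfig()
        lengths = conv_output_lengths(cfg)
        L = 1000
        expected = []
        for K, P in zip((10, 8, 8), (4, 2, 2)):
            L = (L - K + 1) // P
            expected.append(L)
        assert lengths == expected == [247, 120, 56]


class TestPredictProba:
    def test_zero_head_gives_half(self, rng):
        model, cfg, V = tiny_model(rng)
        model.params["out_w"][:] = 0
        model.params["out_b"][:] = 0
        tokens = rng.integers(0, V + 1, size=(5, cfg.max_len))
        np.testing.assert_allclose(predict_proba(tokens, model), 0.5, atol=1e-15)

    def test_probabilities_in_unit_interval_and_complementary(self, rng):
        model, cfg, V = tiny_model(rng)
        p = predict_proba(rng.integers(0, V + 1, size=(20, cfg.max_len)), model)
        assert ((p > 0) & (p < 1)).all()
        # p(y=0) = 1 - p(y=1) holds exactly by construction of the sigmoid pair
        np.testing.assert_allclose(p + (1 - p), 1.0, atol=0)

    def test_monotone_in_head_logit(self, rng):
        model, cfg, V = tiny_model(rng)
        tokens = rng.integers(0, V + 1, size=cfg.max_len)
        p1 = predict_proba(tokens, model)
        model.params["out_b"][:] += 1.0
        assert predict_proba(tokens, model) > p1


class TestEndToEndGradient:
    @pytest.mark.parametrize("variant", ["full", "no_blstm", "no_conv", "dense"])
    def test_cross_entropy_gradient_matches_finite_differences(self, rng, variant):
        kw = {}
        if variant == "no_blstm":
            kw["use_blstm"] = False
        elif variant == "no_conv":
            kw["use_conv"] = False
            kw["conv_filters"] = ()
            kw["conv_kernels"] = ()
            kw["pool_sizes"] = ()
        elif variant == "dense":
            kw["dense_dim"] = 5
        model, cfg, V = tiny_model(rng, **kw)
        X = rng.integers(0, V + 1, size=(4, cfg.max_len))
        y = np.array([0, 1, 1, 0])
        _, grads = loss_and_grads(model, X, y)
        worst = 0.0
        for name, g in grads.items():
            P = model.params[name]
            flat, gflat = P.reshape(-1), g.reshape(-1)
            for pos in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                if name == "emb" and pos < P.shape[1]:
                    continue  # padding row is frozen
                eps, orig = 1e-6, flat[pos]
                flat[pos] = orig + eps
                lp, _ = loss_and_grads(model, X, y)
                flat[pos] = orig - eps
                lm, _ = loss_and_grads(model, X, y)
                flat[pos] = orig
                fd = (lp - lm) / (2 * eps)
                worst = max(worst, abs(fd - gflat[pos]) / max(1e-4, abs(fd), abs(gflat[pos])))
        assert worst < 1e-4


class TestFit:
    def make_separable(self, rng, cfg, V, n=60):
        """Class 1 uses tokens {1,2}, class 0 tokens {3,4}: linearly separable."""
        X = np.empty((n, cfg.max_len), dtype=np.int64)
        y = np.arange(n) % 2
        for i in range(n):
            lo, hi = (1, 3) if y[i] == 1 else (3, 5)
            X[i] = rng.integers(lo, hi, size=cfg.max_len)
        return X, y

    def test_loss_decreases_and_learns_separable_data(self, rng):
        model, cfg, V = tiny_model(rng, seed=3)
        cfg2 = NetworkConfig(**{**cfg.__dict__, "max_epochs": 8, "learning_rate": 0.05,
                                "optimizer": "adam", "batch_size": 16, "val_fraction": 0.15})
        X, y = self.make_separable(rng, cfg2, V)
        log = fit(model, X, y, cfg2)
        assert log[-1]["train_loss"] <= log[0]["train_loss"]
        assert log[-1]["train_acc"] >= 0.9

    def test_same_seed_identical_final_weights(self, rng):
        X = None
        models = []
        for _ in range(2):
            r2 = np.random.default_rng(42)
            model, cfg, V = tiny_model(r2, seed=5)
            cfg2 = NetworkConfig(**{**cfg.__dict__, "max_epochs": 3, "batch_size": 8})
            if X is None:
                X, y0 = self.make_separable(r2, cfg2, V, n=24)
                Xy = (X, y0)
            fit(model, Xy[0], Xy[1], cfg2)
            models.append(model)
        for name in models[0].params:
            np.testing.assert_array_equal(models[0].params[name], models[1].params[name])

    def test_single_class_training_rejected(self, rng):
        model, cfg, V = tiny_model(rng)
        X = rng.integers(1, V + 1, size=(10, cfg.max_len))
        with pytest.raises(ValueError, match="both classes"):
            fit(model, X, np.ones(10, dtype=int), cfg)

    def test_padding_embedding_row_never_updated(self, rng):
        model, cfg, V = tiny_model(rng, seed=3)
        cfg2 = NetworkConfig(**{**cfg.__dict__, "max_epochs": 2, "batch_size": 8})
        X, y = self.make_separable(rng, cfg2, V, n=16)
        X[:, cfg2.max_len // 2 :] = 0  # force padding into every sequence
        fit(model, X, y, cfg2)
        assert (model.params["emb"][0] == 0).all()


class TestConfigValidation:
    def test_mismatched_conv_triples_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            NetworkConfig(conv_filters=(4,), conv_kernels=(3, 3), pool_sizes=(1,))

    def test_double_ablation_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(use_blstm=False, use_conv=False)


def test_model_save_load_roundtrip(tmp_path, rng):
    model, cfg, V = tiny_model(rng)
    model.save(tmp_path / "m.npz")
    back = ClassifierModel.load(tmp_path / "m.npz")
    assert back.config == cfg
    for name in model.params:
        np.testing.assert_array_equal(back.params[name], model.params[name])
    tokens = rng.integers(0, V + 1, size=(3, cfg.max_len))
    np.testing.assert_array_equal(predict_proba(tokens, back), predict_proba(tokens, model))
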