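"""BiLSTM cell mathematics, forward contract, training behaviour."""

import numpy as np
import pytest

from csibreathe import BiLSTMClassifier, NetConfig
from csibreathe import nn as _  # noqa: F401  (re-exported module check)
from csibreathe import classifier as clf_mod
from csibreathe import nn


def tiny_params(rng, D=2, H=3, R=3):
    return nn.init_params(D, H, R, rng)


class TestLstmStep:
    def test_zero_weights_give_zero_hidden_state(self):
        D, H = 4, 3
        params = {"Wx": np.zeros((D, 4 * H)), "Wh": np.zeros((H, 4 * H)), "b": np.zeros(4 * H)}
        h, c = nn.lstm_step(np.ones(D), np.zeros(H), np.zeros(H), params)
        assert np.allclose(h, 0)
        assert np.allclose(c, 0)

    def test_gate_outputs_strictly_inside_unit_interval(self, rng):
        D, H = 3, 5
        Wx = rng.standard_normal((D, 4 * H))
        z = rng.standard_normal((1, 4 * H)) * 10
        g = nn.sigmoid(z)
        assert np.all(g > 0) and np.all(g < 1)
        h, c = nn.lstm_step(rng.standard_normal(D) * 5, rng.standard_normal(H),
                            rng.standard_normal(H),
                            {"Wx": Wx, "Wh": rng.standard_normal((H, 4 * H)),
                             "b": rng.standard_normal(4 * H)})
        assert np.all(np.abs(h) < 1)  # h = o * tanh(c), both bounded

    def test_multi_step_equals_hand_recursion(self, rng):
        # brute-force per-step recursion oracle on a 3-step, 2-unit cell
        D, H, T = 2, 2, 3
        Wx = rng.standard_normal((D, 4 * H))
        Wh = rng.standard_normal((H, 4 * H))
        b = rng.standard_normal(4 * H)
        X = rng.standard_normal((1, T, D))

        def sig(v):
            return 1 / (1 + np.exp(-v))

        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            z = X[0, t] @ Wx + h @ Wh + b
            i, f, g, o = sig(z[:H]), sig(z[H:2 * H]), np.tanh(z[2 * H:3 * H]), sig(z[3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)

        out = nn.lstm_run(X, Wx, Wh, b)[0]
        assert np.allclose(out, h, atol=1e-10)

        # and the public single-step op agrees step by step
        hs, cs = np.zeros(H), np.zeros(H)
        for t in range(T):
            hs, cs = nn.lstm_step(X[0, t], hs, cs, {"Wx": Wx, "Wh": Wh, "b": b})
        assert np.allclose(hs, h, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        params = {"Wx": np.zeros((2, 12)), "Wh": np.zeros((3, 12)), "b": np.zeros(12)}
        with pytest.raises(ValueError):
            nn.lstm_step(np.ones(5), np.zeros(3), np.zeros(3), params)


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        params = tiny_params(rng)
        X = rng.standard_normal((7, 5, 2))
        probs = nn.bilstm_forward(X, params)
        assert np.allclose(probs.sum(axis=1), 1, atol=1e-6)
        assert np.all(probs >= 0)

    def test_zero_weight_model_uniform(self):
        D, H, R = 2, 3, 4
        params = {f"{n}_{d}": np.zeros(s) for d in ("f", "b")
                  for n, s in (("Wx", (D, 4 * H)), ("Wh", (H, 4 * H)), ("b", 4 * H))}
        params["W_out"] = np.zeros((2 * H, R))
        params["b_out"] = np.zeros(R)
        probs = nn.bilstm_forward(np.ones((1, 6, D)), params)
        assert np.allclose(probs, 1 / R)

    def test_sequence_reversal_swaps_direction_roles(self, rng):
        # mirrored parameters oracle: swapping fwd/bwd weights and feeding
        # the reversed sequence swaps the two halves of the readout input
        params = tiny_params(rng)
        X = rng.standard_normal((1, 6, 2))
        hf = nn.lstm_run(X, params["Wx_f"], params["Wh_f"], params["b_f"])
        hb = nn.lstm_run(X[:, ::-1], params["Wx_b"], params["Wh_b"], params["b_b"])
        hf2 = nn.lstm_run(X[:, ::-1], params["Wx_b"], params["Wh_b"], params["b_b"])
        hb2 = nn.lstm_run(X, params["Wx_f"], params["Wh_f"], params["b_f"])
        assert np.allclose(hf2, hb) and np.allclose(hb2, hf)

    def test_empty_sequence_rejected(self, rng):
        params = tiny_params(rng)
        with pytest.raises(ValueError):
            nn.bilstm_forward(np.zeros((1, 0, 2)), params)


class TestGradients:
    def test_analytic_gradient_matches_numerical(self, rng):
        # central-difference check through the full BiLSTM + readout
        B, T, D, H, R = 2, 4, 3, 3, 3
        params = nn.init_params(D, H, R, rng)
        X = rng.standard_normal((B, T, D))
        y = np.array([0, 2])
        probs, cache = nn.bilstm_forward(X, params, return_cache=True)
        grads = nn.bilstm_backward(y, probs, params, cache)
        eps = 1e-6
        worst = 0.0
        for k, v in params.items():
            flat = v.reshape(-1)
            for ix in range(0, flat.size, max(1, flat.size // 8)):
                old = flat[ix]
                flat[ix] = old + eps
                lp = nn.cross_entropy(nn.bilstm_forward(X, params), y)
                flat[ix] = old - eps
                lm = nn.cross_entropy(nn.bilstm_forward(X, params), y)
                flat[ix] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].reshape(-1)[ix]
                worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
        assert worst < 1e-4


class TestTraining:
    @staticmethod
    def toy_dataset(rng, n=40, T=50):
        # sinusoid features at 0.1 Hz vs 0.4 Hz, 10 Hz sampling, no noise
        X = np.empty((n, T, 1))
        y = np.empty(n, dtype=int)
        t = np.arange(T) / 10
        for i in range(n):
            f = 0.1 if i % 2 == 0 else 0.4
            phase = rng.uniform(0, 2 * np.pi)
            X[i, :, 0] = np.sin(2 * np.pi * f * t + phase)
            y[i] = 0 if f == 0.1 else 1
        return X, y

    def test_separable_toy_problem_reaches_100pct_train_accuracy(self, rng):
        X, y = self.toy_dataset(rng)
        clf = BiLSTMClassifier(hidden_units=8, max_epochs=200, patience=200,
                               batch_size=8, random_state=0)
        clf.fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_identical_seed_identical_weights(self, rng):
        X, y = self.toy_dataset(rng, n=16, T=20)
        a = BiLSTMClassifier(hidden_units=4, max_epochs=5, random_state=3).fit(X, y)
        b = BiLSTMClassifier(hidden_units=4, max_epochs=5, random_state=3).fit(X, y)
        for k in a.params_:
            assert np.array_equal(a.params_[k], b.params_[k])

    def test_initial_loss_near_log_R(self, rng):
        # balanced R-class data under a fresh (near-uniform) model
        R = 5
        X = rng.standard_normal((R * 10, 12, 2))
        y = np.repeat(np.arange(R), 10)
        clf = BiLSTMClassifier(hidden_units=10, max_epochs=1, random_state=0).fit(X, y)
        assert clf.loss_curve_[0] == pytest.approx(np.log(R), rel=0.1)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 5, 1))
        with pytest.raises(ValueError):
            BiLSTMClassifier().fit(X, np.zeros(10, dtype=int))

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            NetConfig(hidden_units=0)
        with pytest.raises(ValueError):
            NetConfig(learning_rate=0)
        with pytest.raises(ValueError):
            BiLSTMClassifier(batch_size=0).fit(np.zeros((4, 3, 1)), [0, 1, 0, 1])


class TestPredict:
    def test_argmax_and_tie_break(self):
        assert int(np.argmax([0.1, 0.7, 0.2])) == 1  # class 2 of 3 (index 1)
        assert int(np.argmax([0.5, 0.5])) == 0  # exact tie -> lowest index

    def test_predict_consistent_with_forward_argmax(self, rng):
        # oracle equivalence over many random models
        D, H, R, T = 2, 3, 4, 5
        for trial in range(100):
            r = np.random.default_rng(trial)
            clf = BiLSTMClassifier(hidden_units=H, dtype="float64")
            clf.params_ = nn.init_params(D, H, R, r)
            clf.classes_ = np.arange(R)
            clf.n_features_in_ = D
            clf.n_timesteps_ = T
            seq = r.standard_normal((T, D))
            probs = clf_mod.forward(clf, seq)
            assert clf_mod.predict(clf, seq) == clf.classes_[int(np.argmax(probs))]
            assert probs.sum() == pytest.approx(1, abs=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        X = rng.standard_normal((12, 6, 2))
        y = np.tile([0, 1], 6)
        clf = BiLSTMClassifier(hidden_units=3, max_epochs=2).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(rng.standard_normal((2, 6, 5)))
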