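"""LSTM cell equations, gradients, training behavior, baselines."""

import math

import numpy as np
import pytest

from dynfc.classify import (ClassifierHead, LSTMCellParams, LSTMState,
                            LSTMSequenceClassifier, cell_step,
                            forward_sequence, train_rf_baseline,
                            train_svm_baseline)


def zero_params(H, d):
    z = lambda: np.zeros((H, H + d))
    v = lambda: np.zeros(H)
    return LSTMCellParams(w_f=z(), w_i=z(), w_c=z(), w_o=z(),
                          b_f=v(), b_i=v(), b_c=v(), b_o=v())


class TestCellStep:
    def test_all_zero_weights_zero_state(self):
        p = zero_params(3, 2)
        out = cell_step(p, np.ones(2), LSTMState(np.zeros(3), np.zeros(3)))
        assert np.array_equal(out.h, np.zeros(3))
        assert np.array_equal(out.C, np.zeros(3))

    def test_zero_weights_nonzero_cell(self):
        # sigma(0) = 1/2, candidate tanh(0) = 0: C' = C/2, h = 0.5 tanh(C/2)
        p = zero_params(2, 2)
        c = np.array([0.8, -1.4])
        out = cell_step(p, np.zeros(2), LSTMState(np.zeros(2), c))
        assert np.allclose(out.C, 0.5 * c)
        assert np.allclose(out.h, 0.5 * np.tanh(0.5 * c))

    def test_scalar_hand_evaluation(self):
        # H=1, d=1 with hand-picked weights; oracle written in plain python
        wf, wi, wc, wo = 0.3, -0.2, 0.5, 0.7
        uf, ui, uc, uo = 0.1, 0.4, -0.3, 0.2   # weights on h(t-1)
        bf, bi, bc, bo = 0.05, -0.1, 0.2, 0.0
        h_prev, C_prev, x = 0.3, -0.5, 1.2

        sig = lambda v: 1.0 / (1.0 + math.exp(-v))
        f = sig(uf * h_prev + wf * x + bf)
        i = sig(ui * h_prev + wi * x + bi)
        ct = math.tanh(uc * h_prev + wc * x + bc)
        C = C_prev * f + i * ct
        o = sig(uo * h_prev + wo * x + bo)
        h = o * math.tanh(C)

        p = LSTMCellParams(
            w_f=np.array([[uf, wf]]), w_i=np.array([[ui, wi]]),
            w_c=np.array([[uc, wc]]), w_o=np.array([[uo, wo]]),
            b_f=np.array([bf]), b_i=np.array([bi]),
            b_c=np.array([bc]), b_o=np.array([bo]))
        out = cell_step(p, np.array([x]),
                        LSTMState(np.array([h_prev]), np.array([C_prev])))
        assert out.C[0] == pytest.approx(C, abs=1e-14)
        assert out.h[0] == pytest.approx(h, abs=1e-14)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cell_step(zero_params(2, 3), np.ones(5),
                      LSTMState(np.zeros(2), np.zeros(2)))

    def test_gate_ranges_random_inputs(self, rng):
        # |h| <= 1 elementwise for any weights (sigmoid x tanh product)
        for _ in range(50):
            H, d = rng.integers(1, 6), rng.integers(1, 6)
            p = LSTMCellParams(
                *(rng.standard_normal((H, H + d)) * 3 for _ in range(4)),
                *(rng.standard_normal(H) * 3 for _ in range(4)))
            st = LSTMState(rng.uniform(-1, 1, H), rng.standard_normal(H))
            out = cell_step(p, rng.standard_normal(d) * 5, st)
            assert np.all(np.abs(out.h) <= 1.0)


class TestForwardSequence:
    def test_zero_head_uniform_probabilities(self, rng):
        H, d, n_cls = 4, 3, 3
        p = zero_params(H, d)
        head = ClassifierHead(W1=np.zeros((H, 2)), b1=np.zeros(2),
                              W2=np.zeros((2, n_cls)), b2=np.zeros(n_cls))
        probs = forward_sequence(p, head, rng.standard_normal((d, 6)))
        assert np.allclose(probs, 1.0 / n_cls)

    def test_probabilities_sum_to_one(self, rng):
        H, d = 3, 4
        for _ in range(100):
            p = LSTMCellParams(
                *(rng.standard_normal((H, H + d)) for _ in range(4)),
                *(rng.standard_normal(H) for _ in range(4)))
            head = ClassifierHead(W1=rng.standard_normal((H, 2)),
                                  b1=rng.standard_normal(2),
                                  W2=rng.standard_normal((2, 2)),
                                  b2=rng.standard_normal(2))
            probs = forward_sequence(p, head, rng.standard_normal((d, 5)))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0)

    def test_feature_permutation_equivariance(self, rng):
        H, d = 4, 5
        p = LSTMCellParams(
            *(rng.standard_normal((H, H + d)) for _ in range(4)),
            *(rng.standard_normal(H) for _ in range(4)))
        head = ClassifierHead(W1=rng.standard_normal((H, 3)),
                              b1=rng.standard_normal(3),
                              W2=rng.standard_normal((3, 2)),
                              b2=rng.standard_normal(2))
        seq = rng.standard_normal((d, 7))
        perm = rng.permutation(d)
        p2 = LSTMCellParams(
            w_f=np.concatenate([p.w_f[:, :H], p.w_f[:, H:][:, perm]], axis=1),
            w_i=np.concatenate([p.w_i[:, :H], p.w_i[:, H:][:, perm]], axis=1),
            w_c=np.concatenate([p.w_c[:, :H], p.w_c[:, H:][:, perm]], axis=1),
            w_o=np.concatenate([p.w_o[:, :H], p.w_o[:, H:][:, perm]], axis=1),
            b_f=p.b_f, b_i=p.b_i, b_c=p.b_c, b_o=p.b_o)
        assert np.allclose(forward_sequence(p, head, seq),
                           forward_sequence(p2, head, seq[perm]), atol=1e-12)

    def test_empty_sequence_rejected(self):
        p = zero_params(2, 2)
        head = ClassifierHead(np.zeros((2, 2)), np.zeros(2),
                              np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            forward_sequence(p, head, np.zeros((2, 0)))


class TestGradients:
    @pytest.mark.parametrize("readout", ["last", "mean"])
    def test_finite_difference_agreement(self, readout):
        clf = LSTMSequenceClassifier(hidden_size=4, fc_size=3,
                                     readout=readout, random_state=0)
        rng = np.random.default_rng(1)
        X = [rng.standard_normal((3, 5)), rng.standard_normal((3, 7))]
        y_idx = np.array([0, 1])
        clf.classes_ = np.array([0, 1])
        Xpad, mask = clf._pad(X)
        p = clf._init_params(3, 2, rng)
        _, g = clf._loss_and_grads(Xpad, mask, y_idx, p)
        eps = 1e-6
        for k in p:
            numeric = np.zeros_like(p[k])
            it = np.nditer(p[k], flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                p[k][idx] += eps
                lp, _ = clf._loss_and_grads(Xpad, mask, y_idx, p)
                p[k][idx] -= 2 * eps
                lm, _ = clf._loss_and_grads(Xpad, mask, y_idx, p)
                p[k][idx] += eps
                numeric[idx] = (lp - lm) / (2 * eps)
            rel = np.abs(numeric - g[k]).max() / (np.abs(numeric).max() + 1e-12)
            assert rel < 1e-4, f"gradient mismatch in {k}"


def separable_sequences(n=30, d=10, w=20, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i in range(n):
        s = rng.standard_normal((d, w)) * 0.3
        if i % 2:
            s[2] += shift
        X.append(s)
        y.append(i % 2)
    return X, np.array(y)


class TestTraining:
    def test_separable_reaches_perfect_training_accuracy(self):
        X, y = separable_sequences()
        clf = LSTMSequenceClassifier(random_state=0).fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_seed_determinism(self):
        X, y = separable_sequences(n=16)
        a = LSTMSequenceClassifier(max_epochs=10, random_state=3).fit(X, y)
        b = LSTMSequenceClassifier(max_epochs=10, random_state=3).fit(X, y)
        for k in a._params:
            assert np.array_equal(a._params[k], b._params[k])

    def test_single_class_rejected(self):
        X, _ = separable_sequences(n=6)
        with pytest.raises(ValueError):
            LSTMSequenceClassifier().fit(X, np.zeros(6))

    def test_variable_length_sequences(self):
        rng = np.random.default_rng(4)
        X = [rng.standard_normal((5, rng.integers(8, 20))) for _ in range(12)]
        y = np.arange(12) % 2
        clf = LSTMSequenceClassifier(max_epochs=5, random_state=0).fit(X, y)
        probs = clf.predict_proba(X)
        assert probs.shape == (12, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_permuted_labels_at_chance(self):
        from dynfc.metrics import stratified_kfold
        X, y = separable_sequences(n=40, shift=1.5, seed=5)
        rng = np.random.default_rng(6)
        y_perm = rng.permutation(y)
        folds = stratified_kfold(y_perm, k=5, seed=0)
        accs = []
        for tr, te in folds:
            clf = LSTMSequenceClassifier(max_epochs=40, random_state=0)
            clf.fit([X[i] for i in tr], y_perm[tr])
            accs.append(clf.score([X[i] for i in te], y_perm[te]))
        acc = np.mean(accs)
        half_width = 1.96 * np.sqrt(0.25 / 40)
        assert 0.5 - half_width <= acc <= 0.5 + half_width


class TestPredict:
    def test_uniform_probabilities_tie_break_lowest_class(self):
        X, y = separable_sequences(n=8)
        clf = LSTMSequenceClassifier(max_epochs=2, random_state=0).fit(X, y)
        clf._params["W2"][:] = 0.0
        clf._params["b2"][:] = 0.0
        assert np.all(clf.predict(X[:4]) == clf.classes_[0])

    def test_confident_probability_wins(self):
        X, y = separable_sequences()
        clf = LSTMSequenceClassifier(random_state=0).fit(X, y)
        probs = clf.predict_proba(X)
        pred = clf.predict(X)
        for pr, pd in zip(probs, pred):
            if pr[1] > 0.5:
                assert pd == clf.classes_[1]

    def test_batch_equals_sequential(self):
        X, y = separable_sequences(n=10)
        clf = LSTMSequenceClassifier(max_epochs=5, random_state=1).fit(X, y)
        batch = clf.predict(X)
        single = np.array([clf.predict([x])[0] for x in X])
        assert np.array_equal(batch, single)

    def test_dimension_mismatch_rejected(self):
        X, y = separable_sequences(n=8, d=6)
        clf = LSTMSequenceClassifier(max_epochs=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict([np.zeros((4, 10))])


class TestBaselines:
    def _gaussians(self, n=60, sep=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 8))
        y = np.arange(n) % 2
        X[y == 1, 0] += sep
        return X, y

    def test_separated_gaussians_high_accuracy(self):
        X, y = self._gaussians()
        Xte, yte = self._gaussians(seed=1)
        assert train_svm_baseline(X, y).score(Xte, yte) > 0.95
        assert train_rf_baseline(X, y).score(Xte, yte) > 0.95

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(2)
        X, y = self._gaussians(n=100)
        y_perm = rng.permutation(y)
        from sklearn.model_selection import cross_val_score
        acc = cross_val_score(train_svm_baseline(X[:10], y[:10]), X, y_perm,
                              cv=5).mean()
        half_width = 1.96 * np.sqrt(0.25 / 100)
        assert abs(acc - 0.5) <= half_width + 0.05

    def test_rf_seed_determinism(self):
        X, y = self._gaussians()
        a = train_rf_baseline(X, y, seed=5).predict_proba(X)
        b = train_rf_baseline(X, y, seed=5).predict_proba(X)
        assert np.array_equal(a, b)
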