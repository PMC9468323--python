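"""Sequence classification of dynamic-connectivity features.

The model is a single unidirectional LSTM layer (30 hidden cells by default)
read out at the last valid time step into two fully connected layers with a
rectifier in between and a softmax output.  Writing the gates on the
concatenation z(t) = [h(t-1), X(t)]:

    f(t) = sigma(w_f z(t) + b_f)                 forget gate
    i(t) = sigma(w_i z(t) + b_i)                 input gate
    c~(t) = tanh(w_c z(t) + b_c)                 candidate cell
    C(t) = f(t) * C(t-1) + i(t) * c~(t)
    h(t) = sigma(w_o z(t) + b_o) * tanh(C(t))    output gate x cell

Training minimizes cross-entropy with Adam and backpropagation through time,
implemented directly in NumPy (float64), which keeps the model deterministic
given a seed and makes the analytic gradients directly checkable against
finite differences.  Variable-length sequences are padded at the end and the
cell state is carried unchanged through padded steps, so the readout is
always the last valid hidden state.

Static-feature baselines (linear SVM, random forest) wrap scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LSTMCellParams",
    "LSTMState",
    "ClassifierHead",
    "cell_step",
    "forward_sequence",
    "LSTMSequenceClassifier",
    "train_svm_baseline",
    "train_rf_baseline",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(a, axis=-1):
    a = a - a.max(axis=axis, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class LSTMCellParams:
    """Per-gate weights acting on [h(t-1), x(t)]; each block is (H, H+d)."""
    w_f: np.ndarray
    w_i: np.ndarray
    w_c: np.ndarray
    w_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self):
        return self.w_f.shape[0]

    @property
    def input_size(self):
        return self.w_f.shape[1] - self.w_f.shape[0]


@dataclass
class LSTMState:
    h: np.ndarray
    C: np.ndarray


@dataclass
class ClassifierHead:
    """Two affine layers with a rectifier between and softmax on top."""
    W1: np.ndarray   # (H, H2)
    b1: np.ndarray
    W2: np.ndarray   # (H2, n_classes)
    b2: np.ndarray


def cell_step(params, x_t, prev):
    """One LSTM cell update — the reference (unvectorized) form.

    Kept deliberately close to the gate equations; the estimator uses a
    packed equivalent that is tested against this function.
    """
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape[0] != params.input_size:
        raise ValueError(
            f"input length {x_t.shape[0]} != expected {params.input_size}")
    z = np.concatenate([prev.h, x_t])
    f = _sigmoid(params.w_f @ z + params.b_f)
    i = _sigmoid(params.w_i @ z + params.b_i)
    c_tilde = np.tanh(params.w_c @ z + params.b_c)
    C_new = prev.C * f + i * c_tilde
    o = _sigmoid(params.w_o @ z + params.b_o)
    return LSTMState(h=o * np.tanh(C_new), C=C_new)


def forward_sequence(params, head, seq):
    """Run the cell over the columns of a (d, w) sequence and classify.

    Returns the softmax class probabilities from the final hidden state.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[1] < 1:
        raise ValueError("sequence must be (d, w) with at least one window")
    H = params.hidden_size
    state = LSTMState(h=np.zeros(H), C=np.zeros(H))
    for t in range(seq.shape[1]):
        state = cell_step(params, seq[:, t], state)
    a1 = state.h @ head.W1 + head.b1
    r1 = np.maximum(a1, 0.0)
    return _softmax(r1 @ head.W2 + head.b2)


# ---------------------------------------------------------------------------
# Estimator with BPTT training

class LSTMSequenceClassifier(BaseEstimator, ClassifierMixin):
    """LSTM sequence classifier for (d, w) connectivity feature sequences.

    Parameters
    ----------
    hidden_size : int, default 30
        Number of LSTM cells H.
    fc_size : int, default 16
        Width of the intermediate fully connected layer.
    learning_rate : float, default 1e-3
        Adam step size.
    max_epochs : int, default 200
    batch_size : int, default 16
    patience : int, default 20
        Epochs without improvement of the watched loss (validation loss when
        a holdout exists, else training loss) before early stopping; the
        best-epoch weights are restored.
    loss_tol : float, default 1e-4
        Stop once the epoch training loss falls below this.
    weight_decay : float, default 1e-2
        Decoupled L2 decay applied to weight matrices (not biases).
    input_noise : float, default 2.0
        SD of Gaussian jitter added to (standardized) training inputs each
        batch; regularizes against memorizing subject-specific connectivity
        signatures, which dominate small cohorts.
    validation_fraction : float, default 0.2
        Stratified share of the training set held out to drive early
        stopping (skipped when fewer than 10 sequences).
    readout : {"last", "mean"}, default "last"
        Use the final hidden state or the mean over valid steps.
    random_state : int or None
        Seeds initialization and batch shuffling; same seed + data gives
        bit-identical fitted parameters.

    Attributes
    ----------
    classes_ : sorted unique labels
    cell_params_ : LSTMCellParams (fitted gate weights)
    head_ : ClassifierHead
    loss_history_ : per-epoch training loss
    """

    def __init__(self, hidden_size=30, fc_size=16, learning_rate=1e-3,
                 max_epochs=200, batch_size=16, patience=20, loss_tol=1e-4,
                 weight_decay=1e-2, input_noise=2.0, validation_fraction=0.2,
                 crop_fraction=None, readout="last", random_state=None):
        self.hidden_size = hidden_size
        self.fc_size = fc_size
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.loss_tol = loss_tol
        self.weight_decay = weight_decay
        self.input_noise = input_noise
        self.validation_fraction = validation_fraction
        self.crop_fraction = crop_fraction
        self.readout = readout
        self.random_state = random_state

    # -- parameter packing ---------------------------------------------------

    def _init_params(self, d, n_classes, rng):
        H, H2 = self.hidden_size, self.fc_size

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        W = glorot((H + d, 4 * H))          # gate order: i, f, c~, o
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0                    # forget-gate bias starts open
        W1 = glorot((H, H2))
        b1 = np.zeros(H2)
        W2 = glorot((H2, n_classes))
        b2 = np.zeros(n_classes)
        return {"W": W, "b": b, "W1": W1, "b1": b1, "W2": W2, "b2": b2}

    @staticmethod
    def _to_cell_params(p, H):
        W, b = p["W"], p["b"]
        blocks = {}
        for k, name in enumerate(("i", "f", "c", "o")):
            # packed weights act as z @ W; the per-gate form is w @ z
            blocks[f"w_{name}"] = W[:, k * H:(k + 1) * H].T
            blocks[f"b_{name}"] = b[k * H:(k + 1) * H]
        # reorder concatenation blocks: packed z = [h, x] matches cell_step
        return LSTMCellParams(
            w_f=blocks["w_f"], w_i=blocks["w_i"], w_c=blocks["w_c"],
            w_o=blocks["w_o"], b_f=blocks["b_f"], b_i=blocks["b_i"],
            b_c=blocks["b_c"], b_o=blocks["b_o"])

    # -- forward / backward --------------------------------------------------

    def _forward(self, Xpad, mask, p, cache=False):
        """Xpad: (B, w, d); mask: (B, w) float. Returns probs and cache."""
        B, w, d = Xpad.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        C = np.zeros((B, H))
        steps = []
        hsum = np.zeros((B, H))
        for t in range(w):
            m = mask[:, t][:, None]
            z = np.concatenate([h, Xpad[:, t]], axis=1)
            a = z @ p["W"] + p["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            C_new = f * C + i * g
            tC = np.tanh(C_new)
            h_new = o * tC
            h_next = m * h_new + (1 - m) * h
            C_next = m * C_new + (1 - m) * C
            if cache:
                steps.append((z, i, f, g, o, C, C_new, tC, h, m))
            h, C = h_next, C_next
            hsum += m * h_new
        if self.readout == "mean":
            nvalid = mask.sum(axis=1, keepdims=True)
            hout = hsum / nvalid
        else:
            hout = h
        a1 = hout @ p["W1"] + p["b1"]
        r1 = np.maximum(a1, 0.0)
        logits = r1 @ p["W2"] + p["b2"]
        probs = _softmax(logits, axis=1)
        cc = (steps, hout, a1, r1) if cache else None
        return probs, cc

    def _loss_and_grads(self, Xpad, mask, y_idx, p):
        """Mean cross-entropy and gradients w.r.t. every parameter array."""
        B, w, d = Xpad.shape
        H = self.hidden_size
        probs, (steps, hout, a1, r1) = self._forward(Xpad, mask, p, cache=True)
        eps = 1e-12
        loss = -np.log(probs[np.arange(B), y_idx] + eps).mean()

        dlogits = probs.copy()
        dlogits[np.arange(B), y_idx] -= 1.0
        dlogits /= B
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["W2"] = r1.T @ dlogits
        g["b2"] = dlogits.sum(axis=0)
        dr1 = dlogits @ p["W2"].T
        da1 = dr1 * (a1 > 0)
        g["W1"] = hout.T @ da1
        g["b1"] = da1.sum(axis=0)
        dhout = da1 @ p["W1"].T

        if self.readout == "mean":
            nvalid = mask.sum(axis=1, keepdims=True)
            dh = np.zeros((B, H))
            dC = np.zeros((B, H))
        else:
            dh = dhout
            dC = np.zeros((B, H))
        for t in range(w - 1, -1, -1):
            z, i, f, gg, o, C_prev, C_new, tC, h_prev, m = steps[t]
            if self.readout == "mean":
                dh_new = m * (dhout / nvalid) + m * dh
            else:
                dh_new = m * dh
            dC_new = m * dC
            do = dh_new * tC
            dC_new = dC_new + dh_new * o * (1.0 - tC ** 2)
            df = dC_new * C_prev
            di = dC_new * gg
            dg = dC_new * i
            dC_prev = dC_new * f
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - gg ** 2),
                do * o * (1 - o),
            ], axis=1)
            g["W"] += z.T @ da
            g["b"] += da.sum(axis=0)
            dz = da @ p["W"].T
            if self.readout == "mean":
                dh = dz[:, :H] + (1 - m) * dh
                dC = dC_prev + (1 - m) * dC
            else:
                dh = dz[:, :H] + (1 - m) * dh
                dC = dC_prev + (1 - m) * dC
        return loss, g

    # -- sklearn API ---------------------------------------------------------

    def _pad(self, X):
        lengths = [np.asarray(x).shape[1] for x in X]
        d = np.asarray(X[0]).shape[0]
        w = max(lengths)
        B = len(X)
        Xpad = np.zeros((B, w, d))
        mask = np.zeros((B, w))
        for k, x in enumerate(X):
            x = np.asarray(x, dtype=float)
            if x.shape[0] != d:
                raise ValueError("inconsistent feature dimension across "
                                 "sequences")
            Xpad[k, :x.shape[1]] = x.T
            mask[k, :x.shape[1]] = 1.0
        return Xpad, mask

    def fit(self, X, y):
        if len(X) == 0:
            raise ValueError("empty training set")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training labels contain a single class")
        y_idx = np.searchsorted(self.classes_, y)
        Xpad, mask = self._pad(X)
        B, w, d = Xpad.shape
        self.n_features_in_ = d
        rng = np.random.default_rng(self.random_state)
        p = self._init_params(d, self.classes_.size, rng)

        # stratified validation holdout for early stopping (when feasible)
        val_idx = np.zeros(0, dtype=int)
        if self.validation_fraction and B >= 10:
            per_class = {c: np.flatnonzero(y_idx == k)
                         for k, c in enumerate(self.classes_)}
            parts = []
            for members in per_class.values():
                n_val = max(1, int(round(len(members)
                                         * self.validation_fraction)))
                parts.append(rng.permutation(members)[:n_val])
            val_idx = np.sort(np.concatenate(parts))
        train_pool = np.setdiff1d(np.arange(B), val_idx)

        # Adam state
        mom = {k: np.zeros_like(v) for k, v in p.items()}
        vel = {k: np.zeros_like(v) for k, v in p.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best = np.inf
        best_p = None
        stall = 0
        self.loss_history_ = []
        self.val_loss_history_ = []
        for epoch in range(self.max_epochs):
            order = train_pool[rng.permutation(train_pool.size)]
            ep_loss = 0.0
            nb = 0
            for s0 in range(0, order.size, self.batch_size):
                idx = order[s0:s0 + self.batch_size]
                xb = Xpad[idx]
                mb = mask[idx]
                if self.crop_fraction:
                    # random contiguous sub-sequence per sample (augmentation)
                    mb = mb.copy()
                    for r in range(mb.shape[0]):
                        wi = int(mb[r].sum())
                        li = max(2, int(round(self.crop_fraction * wi)))
                        si = int(rng.integers(0, wi - li + 1)) if wi > li else 0
                        mb[r, :] = 0.0
                        mb[r, si:si + li] = 1.0
                if self.input_noise:
                    xb = xb + self.input_noise * mb[..., None] \
                        * rng.standard_normal(xb.shape)
                loss, grads = self._loss_and_grads(xb, mb, y_idx[idx], p)
                step += 1
                for k in p:
                    mom[k] = b1 * mom[k] + (1 - b1) * grads[k]
                    vel[k] = b2 * vel[k] + (1 - b2) * grads[k] ** 2
                    mhat = mom[k] / (1 - b1 ** step)
                    vhat = vel[k] / (1 - b2 ** step)
                    p[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    if self.weight_decay and not k.startswith("b"):
                        # decoupled weight decay on weights (not biases)
                        p[k] -= self.learning_rate * self.weight_decay * p[k]
                ep_loss += loss
                nb += 1
            ep_loss /= nb
            self.loss_history_.append(ep_loss)
            if val_idx.size:
                vp, _ = self._forward(Xpad[val_idx], mask[val_idx], p)
                watch = -np.log(vp[np.arange(val_idx.size),
                                   y_idx[val_idx]] + 1e-12).mean()
                self.val_loss_history_.append(watch)
            else:
                watch = ep_loss
            if watch < best - 1e-5:
                best = watch
                best_p = {k: v.copy() for k, v in p.items()}
                stall = 0
            else:
                stall += 1
            if ep_loss < self.loss_tol or stall >= self.patience:
                break
        if best_p is not None:
            p = best_p
        self._params = p
        self.cell_params_ = self._to_cell_params(p, self.hidden_size)
        self.head_ = ClassifierHead(W1=p["W1"], b1=p["b1"],
                                    W2=p["W2"], b2=p["b2"])
        self.n_epochs_ = len(self.loss_history_)
        return self

    def predict_proba(self, X):
        if not hasattr(self, "_params"):
            raise RuntimeError("classifier is not fitted")
        Xpad, mask = self._pad(X)
        if Xpad.shape[2] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {Xpad.shape[2]} does not match the "
                f"fitted dimension {self.n_features_in_}")
        probs, _ = self._forward(Xpad, mask, self._params)
        return probs

    def predict(self, X):
        """Argmax class; ties resolve to the lowest class index."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ---------------------------------------------------------------------------
# Static-feature baselines

def train_svm_baseline(X, y, C=1.0, kernel="linear", seed=0):
    """Standardized linear SVM on static connectivity vectors."""
    model = make_pipeline(
        StandardScaler(),
        SVC(C=C, kernel=kernel, random_state=seed))
    return model.fit(np.asarray(X, dtype=float), y)


def train_rf_baseline(X, y, n_estimators=100, seed=0):
    """Random forest (100 trees) on static connectivity vectors."""
    model = RandomForestClassifier(n_estimators=n_estimators,
                                   random_state=seed)
    return model.fit(np.asarray(X, dtype=float), y)
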