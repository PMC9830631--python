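"""BiLSTM respiratory-motion classifier with a scikit-learn interface.

Sequence input -> bidirectional LSTM -> fully connected -> softmax ->
class. Trained with cross-entropy and Adam; default hyperparameters are
50 hidden units, learning rate 0.01, batch size 64.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

__all__ = ["NetConfig", "BiLSTMClassifier", "train", "forward", "predict"]


@dataclass(frozen=True)
class NetConfig:
    """Training hyperparameters for the BiLSTM network."""

    hidden_units: int = 50
    learning_rate: float = 0.01
    batch_size: int = 64
    max_epochs: int = 150
    patience: int = 20
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class BiLSTMClassifier(BaseEstimator, ClassifierMixin):
    """Bidirectional-LSTM sequence classifier.

    Parameters
    ----------
    hidden_units : int, default 50
        LSTM state size per direction.
    learning_rate : float, default 0.01
        Adam step size.
    batch_size : int, default 64
        Mini-batch size (the last batch of an epoch may be smaller).
    max_epochs : int, default 150
        Upper bound on training epochs.
    patience : int, default 20
        Epochs without training-loss improvement (by more than ``tol``)
        before early stopping.
    tol : float, default 1e-4
        Minimum loss improvement that resets patience.
    random_state : int, default 0
        Seed for weight initialization and batch shuffling; identical
        seeds give bit-identical trained weights.
    dtype : {"float32", "float64"}, default "float32"
        Working precision of training and inference. Single precision is
        ample for a classifier readout and about twice as fast; switch to
        float64 for gradient diagnostics.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; internal class index is the position here.
    params_ : dict
        Trained LSTM/readout weight arrays.
    loss_curve_ : list of float
        Full-dataset training loss; entry 0 is the pre-training loss,
        entry e the loss after epoch e.
    n_epochs_ : int
        Number of epochs actually run.
    """

    def __init__(self, hidden_units=50, learning_rate=0.01, batch_size=64,
                 max_epochs=150, patience=20, tol=1e-4, random_state=0,
                 dtype="float32"):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.random_state = random_state
        self.dtype = dtype

    def _validate_X(self, X):
        X = np.asarray(X, dtype=np.dtype(self.dtype))
        if X.ndim != 3:
            raise ValueError("X must be [n_samples, n_steps, n_channels]")
        if X.shape[1] == 0:
            raise ValueError("empty sequences")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        return X

    def fit(self, X, y):
        # validate hyperparameters through the shared config
        NetConfig(hidden_units=self.hidden_units, learning_rate=self.learning_rate,
                  batch_size=self.batch_size, max_epochs=self.max_epochs,
                  patience=self.patience, tol=self.tol, seed=self.random_state)
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        n, T, D = X.shape
        R = len(self.classes_)
        self.n_features_in_ = D
        self.n_timesteps_ = T

        rng = np.random.default_rng(self.random_state)
        params = nn.init_params(D, self.hidden_units, R, rng)
        params = {k: v.astype(X.dtype) for k, v in params.items()}
        opt = nn.AdamOptimizer(params, learning_rate=self.learning_rate)

        # entry 0: full-dataset loss before any update; entry e: full-dataset
        # loss after epoch e. Early stopping monitors this estimate; the
        # final weights are kept (no best-snapshot restore: with a
        # training-loss signal the minimum-loss epoch is the most memorized
        # one, not the best-generalizing one).
        def full_loss():
            return nn.cross_entropy(self._batched_probs(X, params), y_idx)

        self.loss_curve_ = [full_loss()]
        best = self.loss_curve_[0]
        stall = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                probs, cache = nn.bilstm_forward(X[sel], params, return_cache=True)
                grads = nn.bilstm_backward(y_idx[sel], probs, params, cache)
                opt.step(params, grads)
            loss = full_loss()
            self.loss_curve_.append(loss)
            if loss < best - self.tol:
                best = loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.params_ = params
        self.n_epochs_ = len(self.loss_curve_) - 1
        return self

    def _batched_probs(self, X, params, chunk=256):
        out = np.empty((len(X), params["b_out"].shape[0]))
        for s in range(0, len(X), chunk):
            out[s:s + chunk] = nn.bilstm_forward(X[s:s + chunk], params)
        return out

    def predict_proba(self, X):
        self._check_fitted()
        X = self._validate_X(X)
        if X.shape[2] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} channels, got {X.shape[2]}")
        return self._batched_probs(X, self.params_)

    def predict(self, X):
        # argmax over probabilities; np.argmax resolves exact ties to the
        # lowest class index (documented tie-break)
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ValueError("BiLSTMClassifier is not fitted")

    @property
    def config(self) -> NetConfig:
        return NetConfig(hidden_units=self.hidden_units, learning_rate=self.learning_rate,
                         batch_size=self.batch_size, max_epochs=self.max_epochs,
                         patience=self.patience, tol=self.tol, seed=self.random_state)


def train(X, y, cfg: NetConfig | None = None) -> BiLSTMClassifier:
    """Train a BiLSTM classifier; thin functional wrapper over the estimator."""
    cfg = cfg or NetConfig()
    clf = BiLSTMClassifier(hidden_units=cfg.hidden_units, learning_rate=cfg.learning_rate,
                           batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                           patience=cfg.patience, tol=cfg.tol, random_state=cfg.seed)
    return clf.fit(X, y)


def forward(model: BiLSTMClassifier, sequence) -> np.ndarray:
    """Class probabilities (length R) for a single [n_steps, n_channels]
    sequence."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim != 2:
        raise ValueError("sequence must be 2-D [n_steps, n_channels]")
    return model.predict_proba(seq[None])[0]


def predict(model: BiLSTMClassifier, sequence):
    """Predicted class label for a single sequence (argmax of forward;
    ties break to the lowest class index)."""
    probs = forward(model, sequence)
    return model.classes_[int(np.argmax(probs))]
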