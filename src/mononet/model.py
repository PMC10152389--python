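"""MonoNetClassifier: an interpretable-by-construction neural classifier.

The network is an ordinary multilayer perceptron up to a chosen
*interpretable layer*; from there to the output it is built exclusively from
positive-weight ("monotonic") layers bracketed by trainable component-wise
rescalings alpha and beta.  As a consequence every output logit is, by
construction, a monotone function of every interpretable neuron, with
direction ``sign(alpha_i * beta_j)`` — a global, architecture-level guarantee
that survives training because it is structural rather than penalized.

The default architecture mirrors the mass-cytometry case study this model
was designed around: 13 markers -> 16 -> 16 -> 8 (interpretable) ->
pre-monotonic rescaling -> 32 -> 32 -> n_classes.
"""
from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._net import Adam, DenseBlock, MonotonicHead, guard_nonzero, one_hot, softmax
from .errors import DimensionError, TrainingDivergedError
from .monotonic import sign_strength_matrix, sweep_monotonicity

__all__ = ["MonoNetClassifier"]


class MonoNetClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward classifier with a monotonically constrained head.

    Parameters
    ----------
    hidden_sizes:
        Sizes of the unconstrained hidden layers before the interpretable
        layer.
    interpretable_size:
        Width of the interpretable layer; its neurons are the "high-level
        features" every logit is monotone in.
    monotonic_sizes:
        Sizes of the hidden monotonic layers between the interpretable layer
        and the output.
    transform:
        Positive weight transform for the monotonic layers: ``"exponential"``
        (default), ``"square"`` or ``"shifted_tanh"``.
    activation:
        Non-decreasing nonlinearity used throughout (``"tanh"`` default,
        ``"relu"`` allowed).
    epochs, batch_size, learning_rate:
        Adam optimization schedule.
    patience:
        Early-stopping patience, in epochs without validation-accuracy
        improvement.  Ignored when no validation set is available.
    validation_fraction:
        Fraction of the training data held out (stratified) for early
        stopping when ``fit`` is not given an explicit validation set.
    random_state:
        Seed controlling initialization, shuffling and the validation split.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (16, 16),
        interpretable_size: int = 8,
        monotonic_sizes: tuple[int, ...] = (32, 32),
        transform: str = "exponential",
        activation: str = "tanh",
        epochs: int = 150,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        patience: int = 10,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.interpretable_size = interpretable_size
        self.monotonic_sizes = monotonic_sizes
        self.transform = transform
        self.activation = activation
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ setup
    def _initialize(self, n_features: int, n_classes: int, rng: np.random.Generator):
        self.block_ = DenseBlock(
            (n_features, *self.hidden_sizes, self.interpretable_size),
            activation=self.activation,
            rng=rng,
        )
        self.head_ = MonotonicHead(
            self.interpretable_size,
            tuple(self.monotonic_sizes),
            n_classes,
            transform=self.transform,
            activation=self.activation,
            residual=False,
            rng=rng,
        )

    # ------------------------------------------------------------------- fit
    def fit(self, X, y, validation_data: tuple | None = None):
        """Train with Adam on softmax cross-entropy.

        ``validation_data=(X_val, y_val)`` overrides the internal stratified
        hold-out.  The parameters giving the best validation accuracy are
        restored at the end; with ``epochs=0`` the freshly initialized
        parameters are returned untouched.
        """
        X, y = check_X_y(X, y, dtype=float)
        self._le_ = LabelEncoder().fit(y)
        self.classes_ = self._le_.classes_
        y_idx = self._le_.transform(y)
        n_classes = len(self.classes_)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self._initialize(X.shape[1], n_classes, rng)

        if validation_data is not None:
            X_tr, y_tr = X, y_idx
            X_val = check_array(validation_data[0], dtype=float)
            y_val = self._le_.transform(np.asarray(validation_data[1]))
        elif self.validation_fraction and self.epochs > 0 and len(X) >= 10 * n_classes:
            seed = int(rng.integers(2**31 - 1))
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y_idx,
                test_size=self.validation_fraction,
                stratify=y_idx,
                random_state=seed,
            )
        else:
            X_tr, y_tr, X_val, y_val = X, y_idx, None, None

        params = {**{f"u_{k}": v for k, v in self.block_.params.items()},
                  **{f"m_{k}": v for k, v in self.head_.params.items()}}
        opt = Adam(params, lr=self.learning_rate)
        history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        best_val, best_params, stale = -np.inf, None, 0
        Y_tr = one_hot(y_tr, n_classes)

        for epoch in range(self.epochs):
            order = rng.permutation(len(X_tr))
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X_tr[idx], Y_tr[idx]
                _, bcache = self.block_.forward(xb, want_cache=True)
                H = bcache["A"][-1]
                htrace, hcache = self.head_.forward(H, want_cache=True)
                logits = htrace[-1][1]
                probs = softmax(logits)
                loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
                losses.append(loss)
                dlogits = (probs - yb) / len(xb)
                hgrads, dH = self.head_.backward(hcache, dlogits)
                bgrads, _ = self.block_.backward(bcache, dH)
                grads = {**{f"u_{k}": v for k, v in bgrads.items()},
                         **{f"m_{k}": v for k, v in hgrads.items()}}
                opt.step(params, grads)
                guard_nonzero(self.head_.params["alpha"])
                guard_nonzero(self.head_.params["beta"])
            epoch_loss = float(np.mean(losses)) if losses else np.nan
            if not np.isfinite(epoch_loss):
                raise TrainingDivergedError(epoch)
            tr_loss, tr_acc = self._loss_acc(X_tr, y_tr)
            history["train_loss"].append(tr_loss)
            history["train_acc"].append(tr_acc)
            if X_val is not None:
                va_loss, va_acc = self._loss_acc(X_val, y_val)
                history["val_loss"].append(va_loss)
                history["val_acc"].append(va_acc)
                if va_acc > best_val:
                    best_val, stale = va_acc, 0
                    best_params = copy.deepcopy(params)
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
            if self.verbose:
                msg = f"epoch {epoch + 1}: loss {tr_loss:.4f} acc {tr_acc:.4f}"
                if X_val is not None:
                    msg += f" val_acc {history['val_acc'][-1]:.4f}"
                print(msg)

        if best_params is not None:
            for k, v in best_params.items():
                params[k][...] = v
        self.history_ = history
        self.n_iter_ = len(history["train_loss"])
        return self

    def _loss_acc(self, X, y_idx):
        probs = self._predict_proba_raw(X)
        loss = float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12)))
        acc = float(np.mean(probs.argmax(axis=1) == y_idx))
        return loss, acc

    # -------------------------------------------------------------- inference
    @property
    def alpha_(self) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.params["alpha"]

    @property
    def beta_(self) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.params["beta"]

    def _check_X(self, X):
        check_is_fitted(self, "head_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DimensionError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}"
            )
        return X

    def forward_trace(self, X) -> dict[str, np.ndarray]:
        """Ordered layer-name -> activations mapping for a batch.

        Keys: ``input``, ``unconstrained_*``, ``interpretable``,
        ``pre_monotonic``, ``monotonic_*``, ``output`` (logits),
        ``probabilities``.
        """
        X = self._check_X(X)
        btrace, _ = self.block_.forward(X)
        H = btrace[-1][1]
        htrace, _ = self.head_.forward(H)
        trace = {"input": X}
        trace.update(dict(btrace))
        trace.update(dict(htrace))
        trace["probabilities"] = softmax(trace["output"])
        return trace

    def interpretable_activations(self, X) -> np.ndarray:
        btrace, _ = self.block_.forward(self._check_X(X))
        return btrace[-1][1]

    def decision_function(self, X) -> np.ndarray:
        return self.head_.logits(self.interpretable_activations(X))

    def _predict_proba_raw(self, X) -> np.ndarray:
        btrace, _ = self.block_.forward(X)
        return softmax(self.head_.logits(btrace[-1][1]))

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # ---------------------------------------------------------- interpretation
    def sign_strength_matrix(self, neuron_names=None) -> pd.DataFrame:
        """Direction/strength matrix 1/(alpha_i beta_j), neurons x classes."""
        check_is_fitted(self, "head_")
        return sign_strength_matrix(
            self.alpha_, self.beta_,
            neuron_names=neuron_names,
            class_names=[str(c) for c in self.classes_],
        )

    def check_monotonicity(self, X, n_points: int = 21, n_base: int = 100,
                           tol: float = 1e-7, rng=None):
        """Run the finite-difference sweep oracle on this model's head."""
        H = self.interpretable_activations(X)
        return sweep_monotonicity(self.head_, H, n_points=n_points,
                                  n_base=n_base, tol=tol, rng=rng)
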