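"""Monotonic convolutional classifier for small images.

One unconstrained convolutional layer acts as a bank of feature detectors;
from each feature map only the top-k activations (with their locations) are
kept, and these ``n_filters * k`` units form the interpretable layer.  From
there the construction is the tabular one — rescaling alpha, a stack of
positive-weight monotonic layers, output rescaling beta — with one addition:
a *monotonic residual connection*, a single positive-weight linear layer from
the rescaled interpretable units straight to the outputs, summed with the
block.  A sum of two maps monotone in the same directions is again monotone,
so the logit/interpretable-unit contract is unchanged.

Because each interpretable unit is tied to a spatial location (the argmax of
its feature map), an interpretation reads: "the region under this filter's
receptive field provides evidence for/against class c", with the direction
given by ``sign(alpha_i * beta_j)``.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder
from sklearn.utils.validation import check_is_fitted

from ._net import Adam, MonotonicHead, guard_nonzero, one_hot, softmax
from ._transforms import ACTIVATIONS
from .errors import DimensionError, InvalidParameterError, TrainingDivergedError
from .monotonic import sign_strength_matrix, sweep_monotonicity

__all__ = ["MonoCNNClassifier", "topk_pool", "FeatureLocation", "receptive_field"]


@dataclass
class FeatureLocation:
    """Where a filter fired: feature-map coordinates + image-space rectangle."""

    filter_index: int
    row: int
    col: int
    rect: tuple[int, int, int, int]  # (row0, col0, row1, col1), inclusive, image frame


def receptive_field(row: int, col: int, kernel_size: int,
                    stride: int = 1) -> tuple[int, int, int, int]:
    """Image-coordinate rectangle seen by feature-map position (row, col)."""
    r0, c0 = row * stride, col * stride
    return (r0, c0, r0 + kernel_size - 1, c0 + kernel_size - 1)


def topk_pool(feature_map: np.ndarray, k: int, filter_index: int = 0,
              kernel_size: int = 1, stride: int = 1):
    """The k largest activations of a 2-D map, with deterministic ties.

    Returns ``(values, locations)`` with values sorted descending; ties are
    broken in row-major (reading) order, so the output is a pure function of
    the map contents.
    """
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 2:
        raise DimensionError("feature map must be 2-D")
    if not 1 <= k <= fm.size:
        raise InvalidParameterError(f"k must be in [1, {fm.size}], got {k}")
    flat = fm.ravel()
    order = np.argsort(-flat, kind="stable")[:k]
    values = flat[order]
    locs = [
        FeatureLocation(
            filter_index=filter_index,
            row=int(i // fm.shape[1]),
            col=int(i % fm.shape[1]),
            rect=receptive_field(int(i // fm.shape[1]), int(i % fm.shape[1]),
                                 kernel_size, stride),
        )
        for i in order
    ]
    return values, locs


class MonoCNNClassifier(ClassifierMixin, BaseEstimator):
    """Single-conv-layer classifier with a monotonic head and residual.

    Accepts images as ``(n, H, W)`` arrays (or ``(n, H*W)`` flattened, using
    ``image_shape`` to fold them back).  The interpretable layer consists of
    the per-filter top-k activations after the nonlinearity.
    """

    def __init__(
        self,
        image_shape: tuple[int, int] = (28, 28),
        n_filters: int = 32,
        kernel_size: int = 3,
        top_k: int = 4,
        monotonic_sizes: tuple[int, ...] = (32, 32),
        transform: str = "exponential",
        activation: str = "tanh",
        epochs: int = 80,
        batch_size: int = 128,
        learning_rate: float = 3e-3,
        patience: int = 20,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.image_shape = image_shape
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.top_k = top_k
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

    # ------------------------------------------------------------------ plumbing
    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        H, W = self.image_shape
        if X.ndim == 2 and X.shape[1] == H * W:
            X = X.reshape(-1, H, W)
        if X.ndim != 3 or X.shape[1:] != (H, W):
            raise DimensionError(
                f"expected images of shape {self.image_shape}, got array {X.shape}"
            )
        return X

    @property
    def n_interpretable_(self) -> int:
        return self.n_filters * self.top_k

    def _conv_maps(self, images: np.ndarray, want_patches: bool = False):
        """Activation maps (n, F, oh, ow) after the nonlinearity.

        Uses an im2col layout so both passes are single BLAS matmuls.
        """
        n = len(images)
        ks = self.kernel_size
        oh, ow = images.shape[1] - ks + 1, images.shape[2] - ks + 1
        windows = sliding_window_view(images, (ks, ks), axis=(1, 2))
        P = np.ascontiguousarray(windows).reshape(n, oh * ow, ks * ks)
        z = (P @ self.kernel_.reshape(self.n_filters, -1).T + self.conv_bias_)
        z = z.transpose(0, 2, 1).reshape(n, self.n_filters, oh, ow)
        act, _ = ACTIVATIONS[self.activation]
        maps = act(z)
        if want_patches:
            return maps, z, P
        return maps

    def _pool(self, maps: np.ndarray):
        """Batched per-map top-k: returns (h, idx) with h (n, F*k).

        Uses argpartition for speed, then orders the k candidates by
        (value desc, flat index asc) — the same rule as :func:`topk_pool`.
        Exact value ties *at the selection boundary* are resolved by the
        partition, which is immaterial for continuous activations.
        """
        n, F, oh, ow = maps.shape
        k = self.top_k
        flat = maps.reshape(n, F, oh * ow)
        if k >= flat.shape[2]:
            part = np.broadcast_to(np.arange(flat.shape[2]), flat.shape).copy()
        else:
            part = np.argpartition(-flat, k - 1, axis=2)[:, :, :k]
        vals = np.take_along_axis(flat, part, axis=2)
        by_idx = np.argsort(part, axis=2, kind="stable")
        part = np.take_along_axis(part, by_idx, axis=2)
        vals = np.take_along_axis(vals, by_idx, axis=2)
        by_val = np.argsort(-vals, axis=2, kind="stable")
        part = np.take_along_axis(part, by_val, axis=2)
        vals = np.take_along_axis(vals, by_val, axis=2)
        return vals.reshape(n, F * k), part

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, validation_data: tuple | None = None):
        images = self._as_images(X)
        y = np.asarray(y)
        self._le_ = LabelEncoder().fit(y)
        self.classes_ = self._le_.classes_
        y_idx = self._le_.transform(y)
        n_classes = len(self.classes_)
        H, W = self.image_shape
        ks = self.kernel_size
        if ks > min(H, W):
            raise InvalidParameterError("kernel larger than the image")
        oh, ow = H - ks + 1, W - ks + 1
        if self.top_k > oh * ow:
            raise InvalidParameterError("top_k exceeds the feature-map size")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = H * W
        limit = np.sqrt(6.0 / (ks * ks + self.n_filters))
        self.kernel_ = rng.uniform(-limit, limit, size=(self.n_filters, ks, ks))
        self.conv_bias_ = np.zeros(self.n_filters)
        self.head_ = MonotonicHead(
            self.n_interpretable_, tuple(self.monotonic_sizes), n_classes,
            transform=self.transform, activation=self.activation,
            residual=True, rng=rng,
        )

        if validation_data is not None:
            im_tr, y_tr = images, y_idx
            im_val = self._as_images(validation_data[0])
            y_val = self._le_.transform(np.asarray(validation_data[1]))
        elif self.validation_fraction and self.epochs > 0 and len(images) >= 10 * n_classes:
            seed = int(rng.integers(2**31 - 1))
            im_tr, im_val, y_tr, y_val = train_test_split(
                images, y_idx, test_size=self.validation_fraction,
                stratify=y_idx, random_state=seed,
            )
        else:
            im_tr, y_tr, im_val, y_val = images, y_idx, None, None

        params = {"kernel": self.kernel_, "conv_bias": self.conv_bias_,
                  **{f"m_{k}": v for k, v in self.head_.params.items()}}
        opt = Adam(params, lr=self.learning_rate)
        _, dact = ACTIVATIONS[self.activation]
        history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        best_val, best_params, stale = -np.inf, None, 0
        Y_tr = one_hot(y_tr, n_classes)

        for epoch in range(self.epochs):
            order = rng.permutation(len(im_tr))
            losses = []
            n_correct = 0
            for start in range(0, len(order), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = im_tr[idx], Y_tr[idx]
                maps, z, P = self._conv_maps(xb, want_patches=True)
                h, pool_idx = self._pool(maps)
                htrace, hcache = self.head_.forward(h, want_cache=True)
                probs = softmax(htrace[-1][1])
                loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
                losses.append(loss)
                n_correct += int(np.sum(probs.argmax(axis=1) == yb.argmax(axis=1)))
                dlogits = (probs - yb) / len(xb)
                hgrads, dh = self.head_.backward(hcache, dlogits)
                # route pooled gradients back to their spatial positions
                n, F, oh_, ow_ = maps.shape
                dflat = np.zeros((n, F, oh_ * ow_))
                np.put_along_axis(
                    dflat, pool_idx, dh.reshape(n, F, self.top_k), axis=2
                )
                dmaps = dflat * dact(z, maps).reshape(n, F, oh_ * ow_)
                # (F, n*S) @ (n*S, ks^2) -> kernel gradient in one matmul
                D = dmaps.transpose(1, 0, 2).reshape(F, -1)
                gk = (D @ P.reshape(-1, P.shape[2])).reshape(self.kernel_.shape)
                gb = dmaps.sum(axis=(0, 2))
                grads = {"kernel": gk, "conv_bias": gb,
                         **{f"m_{k}": v for k, v in hgrads.items()}}
                opt.step(params, grads)
                guard_nonzero(self.head_.params["alpha"])
                guard_nonzero(self.head_.params["beta"])
            epoch_loss = float(np.mean(losses)) if losses else np.nan
            if not np.isfinite(epoch_loss):
                raise TrainingDivergedError(epoch)
            history["train_loss"].append(epoch_loss)
            # running estimate accumulated over the epoch's minibatches
            history["train_acc"].append(n_correct / len(im_tr))
            if im_val is not None:
                va_acc = float(np.mean(self._predict_idx(im_val) == y_val))
                history["val_acc"].append(va_acc)
                if va_acc > best_val:
                    best_val, stale = va_acc, 0
                    best_params = copy.deepcopy(params)
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
            if self.verbose:
                print(f"epoch {epoch + 1}: loss {epoch_loss:.4f}")

        if best_params is not None:
            for k, v in best_params.items():
                params[k][...] = v
        self.history_ = history
        self.n_iter_ = len(history["train_loss"])
        return self

    # ------------------------------------------------------------------ inference
    @property
    def alpha_(self) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.params["alpha"]

    @property
    def beta_(self) -> np.ndarray:
        check_is_fitted(self, "head_")
        return self.head_.params["beta"]

    def interpretable_activations(self, X) -> np.ndarray:
        check_is_fitted(self, "head_")
        maps = self._conv_maps(self._as_images(X))
        h, _ = self._pool(maps)
        return h

    def forward_trace(self, X) -> dict[str, np.ndarray]:
        """Layer-name -> activations: conv maps, interpretable units, head layers."""
        check_is_fitted(self, "head_")
        images = self._as_images(X)
        maps = self._conv_maps(images)
        h, _ = self._pool(maps)
        htrace, _ = self.head_.forward(h)
        trace = {"input": images.reshape(len(images), -1),
                 "conv_maps": maps, "interpretable": h}
        trace.update(dict(htrace))
        trace["probabilities"] = softmax(trace["output"])
        return trace

    def decision_function(self, X) -> np.ndarray:
        return self.head_.logits(self.interpretable_activations(X))

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def _predict_idx(self, images) -> np.ndarray:
        maps = self._conv_maps(images)
        h, _ = self._pool(maps)
        return self.head_.logits(h).argmax(axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # ------------------------------------------------------------------ interpretation
    def sign_strength_matrix(self):
        """Direction/strength 1/(alpha_i beta_j) for every (unit, class) pair.

        Units are named ``f<filter>_t<rank>``: filter index and top-k rank.
        """
        check_is_fitted(self, "head_")
        names = [f"f{f}_t{t}" for f in range(self.n_filters) for t in range(self.top_k)]
        return sign_strength_matrix(
            self.alpha_, self.beta_, neuron_names=names,
            class_names=[str(c) for c in self.classes_],
        )

    def check_monotonicity(self, X, n_points: int = 21, n_base: int = 100,
                           tol: float = 1e-7, rng=None):
        H = self.interpretable_activations(X)
        return sweep_monotonicity(self.head_, H, n_points=n_points,
                                  n_base=n_base, tol=tol, rng=rng)

    def locate(self, X, filter_index: int) -> list[FeatureLocation]:
        """Top-1 firing location of one filter on each image."""
        maps = self._conv_maps(self._as_images(X))
        locs = []
        for m in maps[:, filter_index]:
            _, loc = topk_pool(m, 1, filter_index=filter_index,
                               kernel_size=self.kernel_size)
            locs.append(loc[0])
        return locs

    def class_defining_filter(self, class_label) -> int:
        """Filter whose top-1 unit couples most strongly to the given class.

        Strength is read from the sign/strength matrix entry of each
        filter's rank-0 unit (largest absolute value wins).
        """
        ss = self.sign_strength_matrix()
        col = ss[str(class_label)].to_numpy()
        top1 = col[:: self.top_k]  # rank-0 unit of each filter
        return int(np.argmax(np.abs(top1)))

    def interpret_feature(self, image, filter_index: int) -> dict:
        """Everything needed for a 'region R is evidence for class c' readout."""
        check_is_fitted(self, "head_")
        image = self._as_images(np.asarray(image)[None, ...] if np.asarray(image).ndim == 2
                                else image)[0]
        maps = self._conv_maps(image[None, ...])
        _, locs = topk_pool(maps[0, filter_index], 1, filter_index=filter_index,
                            kernel_size=self.kernel_size)
        ss = self.sign_strength_matrix()
        unit = filter_index * self.top_k  # the filter's top-1 interpretable unit
        return {
            "kernel": self.kernel_[filter_index].copy(),
            "location": locs[0],
            "sign_strength": ss.iloc[unit],
        }
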