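"""Numpy implementation of the monotonic network internals.

The architecture factors into two halves:

* an *unconstrained block* (ordinary dense layers) whose last layer is the
  interpretable layer ``h``;
* a *monotonic head*: component-wise rescaling ``h~ = alpha * h``, a stack of
  positive-weight ("monotonic") layers, a linear positive-weight output layer
  producing ``y~``, and output rescaling ``y = beta * y~``.

Because every effective weight in the head is non-negative and every
activation offered is non-decreasing, each logit ``y_j`` is monotone in each
interpretable neuron ``h_i`` with direction ``sign(alpha_i * beta_j)``.  The
head optionally carries a *monotonic residual connection* (a single
positive-weight linear layer from ``h~`` straight to ``y~``); a sum of
monotone maps with a common direction is again monotone.

Everything is plain float64 numpy; gradients are computed analytically and
optimized with Adam.  This keeps the package dependency-light and the
monotonic construction fully transparent.
"""
from __future__ import annotations

import numpy as np

from ._transforms import ACTIVATIONS, WEIGHT_TRANSFORMS, transform_grad
from .errors import DimensionError, InvalidParameterError

RESCALE_EPS = 1e-12  # alpha/beta entries are kept at least this far from zero
_INIT_RESAMPLE_BAND = 1e-3


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _raw_monotonic_init(
    rng: np.random.Generator, fan_out: int, fan_in: int, transform: str
) -> np.ndarray:
    """Draw raw weights so the *transformed* weights start near 1/fan_in."""
    target = 1.0 / fan_in
    if transform == "exponential":
        return rng.normal(np.log(target), 0.5, size=(fan_out, fan_in))
    if transform == "square":
        return rng.normal(0.0, np.sqrt(target), size=(fan_out, fan_in))
    # shifted_tanh: tanh(v) + 1 = target  =>  v = atanh(target - 1)
    center = np.arctanh(np.clip(target - 1.0, -0.999, 0.999))
    return rng.normal(center, 0.3, size=(fan_out, fan_in))


def _sample_rescaling(rng: np.random.Generator, size: int) -> np.ndarray:
    """Standard-normal draws, resampling anything inside the degenerate band."""
    v = rng.standard_normal(size)
    for _ in range(100):
        bad = np.abs(v) < _INIT_RESAMPLE_BAND
        if not bad.any():
            break
        v[bad] = rng.standard_normal(bad.sum())
    return v


def guard_nonzero(v: np.ndarray) -> np.ndarray:
    """Push exact/near-zero rescaling entries to +/- RESCALE_EPS in place."""
    bad = np.abs(v) < RESCALE_EPS
    if bad.any():
        sign = np.sign(v[bad])
        sign[sign == 0] = 1.0
        v[bad] = sign * RESCALE_EPS
    return v


class MonotonicHead:
    """Rescaling + positive-weight stack (+ optional residual) from h to logits."""

    def __init__(
        self,
        n_interpretable: int,
        monotonic_sizes: tuple[int, ...],
        n_outputs: int,
        transform: str = "exponential",
        activation: str = "tanh",
        residual: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if transform not in WEIGHT_TRANSFORMS:
            raise InvalidParameterError(f"unknown transform {transform!r}")
        if activation not in ACTIVATIONS:
            raise InvalidParameterError(f"unknown activation {activation!r}")
        if n_interpretable < 1 or n_outputs < 1 or any(s < 1 for s in monotonic_sizes):
            raise InvalidParameterError("all layer sizes must be >= 1")
        rng = rng or np.random.default_rng()
        self.n_interpretable = int(n_interpretable)
        self.monotonic_sizes = tuple(int(s) for s in monotonic_sizes)
        self.n_outputs = int(n_outputs)
        self.transform = transform
        self.activation = activation
        self.residual = bool(residual)

        chain = [self.n_interpretable, *self.monotonic_sizes, self.n_outputs]
        self.params: dict[str, np.ndarray] = {
            "alpha": _sample_rescaling(rng, self.n_interpretable),
            "beta": _sample_rescaling(rng, self.n_outputs),
        }
        for l, (fi, fo) in enumerate(zip(chain[:-1], chain[1:])):
            self.params[f"V{l}"] = _raw_monotonic_init(rng, fo, fi, transform)
            self.params[f"c{l}"] = np.zeros(fo)
        if self.residual:
            self.params["Vr"] = _raw_monotonic_init(
                rng, self.n_outputs, self.n_interpretable, transform
            )
        self.n_layers = len(chain) - 1

    # ---------------------------------------------------------------- forward
    def forward(self, H: np.ndarray, want_cache: bool = False):
        """Map interpretable activations (n, p) to logits (n, q).

        Returns ``(trace, cache)``; ``trace`` is an ordered list of
        (layer name, activations) including the pre-monotonic rescaled layer,
        each hidden monotonic layer, and the output logits.
        """
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != self.n_interpretable:
            raise DimensionError(
                f"expected {self.n_interpretable} interpretable activations, got {H.shape[1]}"
            )
        act, _ = ACTIVATIONS[self.activation]
        tfun, _ = WEIGHT_TRANSFORMS[self.transform]
        p = self.params
        Ht = H * p["alpha"]
        trace = [("pre_monotonic", Ht)]
        cache = {"H": H, "Ht": Ht, "T": [], "Z": [], "A": [Ht]}
        a = Ht
        for l in range(self.n_layers):
            T = tfun(p[f"V{l}"])
            z = a @ T.T + p[f"c{l}"]
            if l < self.n_layers - 1:
                a = act(z)
                trace.append((f"monotonic_{l + 1}", a))
            else:
                a = z  # linear output layer
            cache["T"].append(T)
            cache["Z"].append(z)
            cache["A"].append(a)
        ytilde = a
        if self.residual:
            Tr = tfun(p["Vr"])
            ytilde = ytilde + Ht @ Tr.T
            cache["Tr"] = Tr
        logits = ytilde * p["beta"]
        cache["ytilde"] = ytilde
        trace.append(("output", logits))
        return trace, (cache if want_cache else None)

    def logits(self, H: np.ndarray) -> np.ndarray:
        trace, _ = self.forward(H)
        return trace[-1][1]

    # --------------------------------------------------------------- backward
    def backward(self, cache: dict, dlogits: np.ndarray):
        """Gradients of the loss w.r.t. head parameters and w.r.t. H."""
        p = self.params
        _, dact = ACTIVATIONS[self.activation]
        grads: dict[str, np.ndarray] = {}
        grads["beta"] = (dlogits * cache["ytilde"]).sum(axis=0)
        dyt = dlogits * p["beta"]

        dHt = np.zeros_like(cache["Ht"])
        if self.residual:
            grads["Vr"] = transform_grad(p["Vr"], cache["Tr"], self.transform) * (
                dyt.T @ cache["Ht"]
            )
            dHt += dyt @ cache["Tr"]

        da = dyt
        for l in range(self.n_layers - 1, -1, -1):
            if l < self.n_layers - 1:
                dz = da * dact(cache["Z"][l], cache["A"][l + 1])
            else:
                dz = da  # linear output layer
            T = cache["T"][l]
            dT = dz.T @ cache["A"][l]
            grads[f"V{l}"] = transform_grad(p[f"V{l}"], T, self.transform) * dT
            grads[f"c{l}"] = dz.sum(axis=0)
            da = dz @ T
        dHt += da
        grads["alpha"] = (dHt * cache["H"]).sum(axis=0)
        dH = dHt * p["alpha"]
        return grads, dH


class DenseBlock:
    """Plain (unconstrained) dense stack with a shared activation."""

    def __init__(
        self,
        sizes: tuple[int, ...],
        activation: str = "tanh",
        rng: np.random.Generator | None = None,
    ):
        if any(s < 1 for s in sizes):
            raise InvalidParameterError("all layer sizes must be >= 1")
        rng = rng or np.random.default_rng()
        self.sizes = tuple(int(s) for s in sizes)
        self.activation = activation
        self.params: dict[str, np.ndarray] = {}
        for l, (fi, fo) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            self.params[f"W{l}"] = _glorot(rng, fo, fi)
            self.params[f"b{l}"] = np.zeros(fo)
        self.n_layers = len(self.sizes) - 1

    def forward(self, X: np.ndarray, want_cache: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.sizes[0]:
            raise DimensionError(f"expected {self.sizes[0]} input columns, got {X.shape[1]}")
        act, _ = ACTIVATIONS[self.activation]
        trace = []
        cache = {"A": [X], "Z": []}
        a = X
        for l in range(self.n_layers):
            z = a @ self.params[f"W{l}"].T + self.params[f"b{l}"]
            a = act(z)
            cache["Z"].append(z)
            cache["A"].append(a)
            name = "interpretable" if l == self.n_layers - 1 else f"unconstrained_{l + 1}"
            trace.append((name, a))
        return trace, (cache if want_cache else None)

    def backward(self, cache: dict, dOut: np.ndarray):
        _, dact = ACTIVATIONS[self.activation]
        grads: dict[str, np.ndarray] = {}
        da = dOut
        for l in range(self.n_layers - 1, -1, -1):
            dz = da * dact(cache["Z"][l], cache["A"][l + 1])
            grads[f"W{l}"] = dz.T @ cache["A"][l]
            grads[f"b{l}"] = dz.sum(axis=0)
            da = dz @ self.params[f"W{l}"]
        return grads, da


class Adam:
    """Adam over a dict of parameter arrays (keys shared with the grads dict)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
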