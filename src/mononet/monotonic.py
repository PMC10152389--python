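"""Monotonic building blocks and the empirical monotonicity check.

The central construction: a dense layer whose weight matrix is passed through
a positive element-wise transform is monotonically non-decreasing in every
input, provided the activation is non-decreasing.  Stacks of such layers stay
monotone, and bracketing the stack with component-wise rescalings
``h~ = alpha * h`` and ``y = beta * y~`` lets each (interpretable neuron,
output) pair take an arbitrary monotone direction, namely
``sign(alpha_i * beta_j)``.  The entry ``1/(alpha_i beta_j)`` summarizes the
direction and strength of that relationship.

`sweep_monotonicity` is the executable form of the guarantee: single
coordinate grid sweeps of the interpretable-layer-to-logit map must never
move against the prescribed direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._net import MonotonicHead
from ._transforms import ACTIVATIONS, transform_weights
from .errors import DegenerateRescalingError, DimensionError, EmptySampleError

__all__ = [
    "transform_weights",
    "monotonic_layer_forward",
    "sign_strength_matrix",
    "sweep_monotonicity",
    "SweepResult",
]

SIGN_STRENGTH_EPS = 1e-12


def monotonic_layer_forward(
    h: np.ndarray,
    raw_weights: np.ndarray,
    bias: np.ndarray,
    transform: str = "exponential",
    activation: str = "tanh",
) -> np.ndarray:
    """One monotonic layer: ``activation(transform(W) @ h + b)``.

    ``h`` may be a single vector (returns a vector) or a (n, d) batch.
    The output is component-wise non-decreasing in every component of ``h``.
    """
    h = np.asarray(h, dtype=float)
    raw_weights = np.asarray(raw_weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    single = h.ndim == 1
    H = np.atleast_2d(h)
    if H.shape[1] != raw_weights.shape[1]:
        raise DimensionError(
            f"input has {H.shape[1]} features but weights expect {raw_weights.shape[1]}"
        )
    T = transform_weights(raw_weights, transform)
    act, _ = ACTIVATIONS[activation]
    out = act(H @ T.T + bias)
    return out[0] if single else out


def sign_strength_matrix(
    alpha: np.ndarray,
    beta: np.ndarray,
    neuron_names: list[str] | None = None,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Direction/strength matrix with entry (i, j) = 1 / (alpha_i * beta_j).

    The sign of each entry is the monotone direction of logit j in
    interpretable neuron i; the magnitude grows as the rescaling shrinks,
    i.e. as one unit of h_i translates to less movement in y_j.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    prod = np.outer(alpha, beta)
    bad = np.argwhere(np.abs(prod) < SIGN_STRENGTH_EPS)
    if len(bad):
        i, j = bad[0]
        raise DegenerateRescalingError(
            f"|alpha_{i} * beta_{j}| = {abs(prod[i, j]):.3e} < {SIGN_STRENGTH_EPS:g}; "
            "rescaling is degenerate for this (neuron, class) pair"
        )
    values = 1.0 / prod
    idx = neuron_names or [f"neuron_{i}" for i in range(len(alpha))]
    cols = class_names or [f"class_{j}" for j in range(len(beta))]
    return pd.DataFrame(values, index=idx, columns=cols)


@dataclass
class SweepResult:
    """Outcome of the finite-difference monotonicity sweep."""

    n_violations: int
    worst_violation: float  # most negative signed step along the required direction
    n_checks: int  # (neuron, logit, base point, grid step) tuples examined

    @property
    def passed(self) -> bool:
        return self.n_violations == 0


def sweep_monotonicity(
    head: MonotonicHead,
    h_reference: np.ndarray,
    n_points: int = 21,
    n_base: int = 100,
    tol: float = 1e-7,
    rng: np.random.Generator | int | None = None,
) -> SweepResult:
    """Grid-sweep check that logits move only in the direction sign(alpha_i beta_j).

    For every interpretable neuron i, ``n_base`` random base points are drawn
    coordinate-wise from the empirical range of ``h_reference``; coordinate i
    is then swept over an ``n_points`` grid spanning that neuron's range while
    the other coordinates stay fixed.  Along the grid, logit j must be
    non-decreasing when ``alpha_i * beta_j > 0`` and non-increasing otherwise,
    up to ``tol``.
    """
    rng = np.random.default_rng(rng)
    H = np.atleast_2d(np.asarray(h_reference, dtype=float))
    if H.shape[0] == 0:
        raise EmptySampleError("h_reference must contain at least one row")
    if H.shape[1] != head.n_interpretable:
        raise DimensionError(
            f"h_reference has {H.shape[1]} columns, head expects {head.n_interpretable}"
        )
    lo, hi = H.min(axis=0), H.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    direction = np.sign(np.outer(head.params["alpha"], head.params["beta"]))

    n_violations = 0
    worst = 0.0
    n_checks = 0
    for i in range(head.n_interpretable):
        base = lo + rng.random((n_base, head.n_interpretable)) * span
        grid = np.linspace(lo[i] - 0.0, hi[i], n_points)
        if hi[i] == lo[i]:
            grid = np.linspace(lo[i] - 0.5, lo[i] + 0.5, n_points)
        batch = np.repeat(base, n_points, axis=0)
        batch[:, i] = np.tile(grid, n_base)
        logits = head.logits(batch).reshape(n_base, n_points, head.n_outputs)
        steps = np.diff(logits, axis=1)  # (n_base, n_points-1, q)
        signed = steps * direction[i]  # required to be >= -tol everywhere
        n_checks += signed.size
        viol = signed < -tol
        n_violations += int(viol.sum())
        if signed.size:
            worst = min(worst, float(signed.min()))
    return SweepResult(n_violations=n_violations, worst_violation=worst, n_checks=n_checks)
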