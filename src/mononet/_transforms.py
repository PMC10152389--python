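"""Positive weight transforms and non-decreasing activations.

A monotonic layer stores an unconstrained raw matrix ``V`` and uses
``t(V)`` as its effective weight, where ``t`` maps the reals into the
non-negative numbers element-wise.  Any such ``t`` combined with a
non-decreasing activation makes the layer output non-decreasing in every
input coordinate.
"""
from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

# kind -> (transform, derivative wrt raw weight).  The derivative receives
# (raw, transformed) so the exponential can reuse its own output.
WEIGHT_TRANSFORMS = {
    "exponential": (np.exp, lambda V, T: T),
    "square": (np.square, lambda V, T: 2.0 * V),
    "shifted_tanh": (
        lambda V: np.tanh(V) + 1.0,
        lambda V, T: 1.0 - (T - 1.0) ** 2,  # sech^2 = 1 - tanh^2
    ),
}

# name -> (function, derivative as a function of (pre-activation, activation))
ACTIVATIONS = {
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
}


def transform_weights(raw: np.ndarray, transform: str = "exponential") -> np.ndarray:
    """Map a raw real matrix to the non-negative effective weight matrix.

    Parameters
    ----------
    raw:
        Any real array.  Must be finite.
    transform:
        One of ``"exponential"`` (strictly positive output), ``"square"`` or
        ``"shifted_tanh"`` (range [0, 2]).

    Returns
    -------
    Array of the same shape with all entries >= 0.
    """
    raw = np.asarray(raw, dtype=float)
    if transform not in WEIGHT_TRANSFORMS:
        raise InvalidParameterError(
            f"unknown transform {transform!r}; choose from {sorted(WEIGHT_TRANSFORMS)}"
        )
    if not np.all(np.isfinite(raw)):
        raise InvalidParameterError("raw weight matrix contains non-finite entries")
    return WEIGHT_TRANSFORMS[transform][0](raw)


def transform_grad(raw: np.ndarray, transformed: np.ndarray, transform: str) -> np.ndarray:
    """Element-wise derivative d t(V) / dV, used by backprop."""
    return WEIGHT_TRANSFORMS[transform][1](raw, transformed)
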