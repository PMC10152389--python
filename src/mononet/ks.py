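"""Statistical analysis of interpretable-neuron activation patterns.

For each interpretable neuron, cells are ranked by activation; the marker
distributions of the top and bottom fractions (20% by default) are compared
with the two-sample Kolmogorov–Smirnov score
``D = max_x |ECDF_top(x) - ECDF_bottom(x)|``.  A neuron that has specialized
in recognizing a marker separates that marker's top/bottom distributions and
earns a high score; averaging scores over neurons gives a global per-marker
importance.  Directions (+1/-1) record whether the marker's median is higher
in the top- or bottom-activating cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySampleError, InvalidParameterError

__all__ = [
    "ecdf_value",
    "ks_score",
    "rank_split",
    "neuron_marker_ks",
    "global_importance",
    "KSMatrix",
]


def ecdf_value(sample, x: float) -> float:
    """Empirical CDF of ``sample`` at ``x``: #{elements <= x} / n.

    Right-continuous step function, the building block of the KS score.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size == 0:
        raise EmptySampleError("ECDF of an empty sample is undefined")
    return float(np.count_nonzero(sample <= x)) / sample.size


def ks_score(a, b) -> float:
    """Two-sample KS statistic: max |ECDF_a - ECDF_b| over pooled points.

    Symmetric in its arguments, lies in [0, 1], and is 0 exactly when the
    two empirical distributions coincide.  Ties are handled by evaluating
    both ECDFs at every pooled sample point with the <= convention.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise EmptySampleError("KS score requires two non-empty samples")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(cdf_a - cdf_b)))


def rank_split(activations, fraction: float = 0.2):
    """Indices of the top- and bottom-activating cells for one neuron.

    Both sets have exactly ``floor(fraction * n)`` members and are disjoint;
    every top activation is >= every bottom activation.  Ties at either cut
    are resolved by a stable sort on (activation, original index), making the
    split deterministic.
    """
    if not 0.0 < fraction <= 0.5:
        raise InvalidParameterError("fraction must lie in (0, 0.5]")
    activations = np.asarray(activations, dtype=float).ravel()
    n = activations.size
    k = int(np.floor(fraction * n))
    if k < 1:
        raise InvalidParameterError(
            f"fraction {fraction} of {n} cells selects no cell; need n >= {int(np.ceil(1 / fraction))}"
        )
    order = np.argsort(activations, kind="stable")
    return order[n - k:], order[:k]


@dataclass
class KSMatrix:
    """Interpretable-neurons x markers KS scores with direction signs."""

    scores: pd.DataFrame  # values in [0, 1]
    directions: pd.DataFrame  # entries in {-1, 0, +1}
    fraction: float
    constant_neurons: list = field(default_factory=list)

    @property
    def neurons(self) -> list:
        return list(self.scores.index)

    @property
    def markers(self) -> list:
        return list(self.scores.columns)

    def top_markers(self, neuron, k: int = 4) -> list:
        """The k markers with the highest KS score for one neuron."""
        return list(self.scores.loc[neuron].sort_values(ascending=False).index[:k])


def neuron_marker_ks(model, X, fraction: float = 0.2,
                     marker_names=None) -> KSMatrix:
    """KS score of every (interpretable neuron, marker) pair.

    For each neuron the cells are ranked by activation, the top and bottom
    ``fraction`` are selected, and each marker's distribution is compared
    between the two subsets.  Neurons with constant activation still get a
    deterministic tie-broken split but are flagged in ``constant_neurons``.
    """
    if isinstance(X, pd.DataFrame):
        marker_names = marker_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        raise EmptySampleError("marker table is empty")
    marker_names = marker_names or [f"marker_{j}" for j in range(X.shape[1])]
    H = model.interpretable_activations(X)
    neurons = [f"neuron_{i}" for i in range(H.shape[1])]
    scores = np.zeros((H.shape[1], X.shape[1]))
    directions = np.zeros_like(scores)
    constant = []
    for i in range(H.shape[1]):
        if np.ptp(H[:, i]) == 0.0:
            constant.append(neurons[i])
        top, bottom = rank_split(H[:, i], fraction)
        for j in range(X.shape[1]):
            a, b = X[top, j], X[bottom, j]
            scores[i, j] = ks_score(a, b)
            directions[i, j] = np.sign(np.median(a) - np.median(b))
    return KSMatrix(
        scores=pd.DataFrame(scores, index=neurons, columns=marker_names),
        directions=pd.DataFrame(directions, index=neurons, columns=marker_names),
        fraction=fraction,
        constant_neurons=constant,
    )


def global_importance(matrix) -> pd.Series:
    """Per-marker mean score across interpretable neurons.

    Accepts a :class:`KSMatrix` (means of KS scores) or an attribution
    matrix / plain DataFrame, in which case absolute values are averaged.
    """
    if isinstance(matrix, KSMatrix):
        df = matrix.scores
    else:
        df = getattr(matrix, "values_frame", None)
        if df is None:
            df = pd.DataFrame(matrix)
        df = df.abs()
    if df.empty:
        raise EmptySampleError("cannot average an empty matrix")
    out = df.mean(axis=0)
    out.name = "importance"
    return out
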