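"""Where does the classification happen? Layer-wise information analyses.

Two complementary views:

* :func:`ami_profile` clusters the per-cell activations of every recorded
  layer with two different algorithms (K-means and BIRCH) and measures the
  adjusted mutual information between each clustering and the model's
  predicted labels (and, for reference, the true labels).  If the monotonic
  block contributes to the decision, the AMI should rise from the
  interpretable layer toward the output layer.
* :func:`activation_summary` reports per-layer, per-class mean and
  mean-absolute activations; a sharp rise in absolute activation inside the
  monotonic block is the signature of the block actively separating classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import Birch, KMeans
from sklearn.metrics import adjusted_mutual_info_score

from .errors import DimensionError, MissingLabelsError

__all__ = [
    "adjusted_mutual_information",
    "ami_profile",
    "activation_summary",
    "AMIProfile",
    "ActivationSummary",
]


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """AMI between two labelings: (MI - E[MI]) / (mean(H_a, H_b) - E[MI]).

    The expectation is taken under the permutation model, so chance-level
    agreement scores ~0; identical labelings (up to renaming) score 1.
    """
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.size != labels_b.size:
        raise DimensionError(
            f"label vectors differ in length ({labels_a.size} vs {labels_b.size})"
        )
    if labels_a.size < 2:
        raise DimensionError("need at least 2 samples")
    return float(adjusted_mutual_info_score(labels_a, labels_b,
                                            average_method="arithmetic"))


@dataclass
class AMIProfile:
    """AMI of each layer's clustering vs predicted and true labels."""

    values: pd.DataFrame  # rows = layers (network order), columns = clusterer/reference
    n_clusters: int
    seed: int | None
    zero_variance_layers: list = field(default_factory=list)

    @property
    def layers(self) -> list:
        return list(self.values.index)


_EXCLUDE_LAYERS = {"probabilities"}


def ami_profile(model, X, y, n_clusters: int | None = None,
                seed: int | None = 0) -> AMIProfile:
    """Cluster every layer's activations and score AMI against labels.

    Each recorded layer (input through output logits) is clustered with
    K-means and with BIRCH into ``n_clusters`` groups (default: the number
    of classes), and each clustering is compared with the model's predicted
    labels and with the true labels.  A zero-variance layer cannot be
    clustered; its AMI is reported as 0 and the layer flagged.
    """
    if y is None:
        raise MissingLabelsError("ami_profile requires true labels")
    y = np.asarray(y)
    trace = model.forward_trace(X)
    pred = model.classes_[trace["probabilities"].argmax(axis=1)]
    k = n_clusters or len(model.classes_)
    rows, flagged = [], []
    layer_names = [n for n in trace if n not in _EXCLUDE_LAYERS]
    for name in layer_names:
        A = trace[name]
        entry = {}
        if np.allclose(A.var(axis=0), 0.0):
            flagged.append(name)
            for clusterer in ("kmeans", "birch"):
                entry[f"{clusterer}_vs_predicted"] = 0.0
                entry[f"{clusterer}_vs_true"] = 0.0
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(A)
            bi = Birch(n_clusters=k).fit_predict(A)
            for clusterer, lab in (("kmeans", km), ("birch", bi)):
                entry[f"{clusterer}_vs_predicted"] = adjusted_mutual_information(lab, pred)
                entry[f"{clusterer}_vs_true"] = adjusted_mutual_information(lab, y)
        rows.append(pd.Series(entry, name=name))
    return AMIProfile(
        values=pd.DataFrame(rows),
        n_clusters=k,
        seed=seed,
        zero_variance_layers=flagged,
    )


@dataclass
class ActivationSummary:
    """Per-layer, per-class mean and mean-absolute activations."""

    mean: pd.DataFrame  # rows = layers, columns = classes
    mean_abs: pd.DataFrame
    missing_classes: list = field(default_factory=list)

    @property
    def layers(self) -> list:
        return list(self.mean.index)


def activation_summary(model, X, y) -> ActivationSummary:
    """Mean and mean-|.| activation of each layer stratified by class.

    The per-layer value for a class is the grand mean over that class's
    cells and the layer's neurons.  Classes known to the model but absent
    from the table are omitted and listed in ``missing_classes``.
    """
    if y is None:
        raise MissingLabelsError("activation_summary requires class labels")
    y = np.asarray(y)
    trace = model.forward_trace(X)
    layer_names = [n for n in trace if n not in _EXCLUDE_LAYERS]
    present = [c for c in model.classes_ if np.any(y == c)]
    missing = [c for c in model.classes_ if c not in present]
    mean = pd.DataFrame(index=layer_names, columns=present, dtype=float)
    mean_abs = pd.DataFrame(index=layer_names, columns=present, dtype=float)
    for name in layer_names:
        A = trace[name]
        for c in present:
            sel = A[y == c]
            mean.loc[name, c] = float(sel.mean())
            mean_abs.loc[name, c] = float(np.abs(sel).mean())
    return ActivationSummary(mean=mean, mean_abs=mean_abs, missing_classes=missing)
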