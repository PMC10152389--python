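"""Data splitting, training and evaluation helpers.

These are thin wrappers around :class:`~mononet.model.MonoNetClassifier`
(and scikit-learn's splitting utilities) so the train/evaluate workflow can
be scripted without touching estimator internals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .errors import MissingLabelsError, StratificationError

__all__ = ["SplitSpec", "split_data", "train", "evaluate"]


@dataclass
class SplitSpec:
    """Three-way split: test fraction first, then validation out of training.

    Defaults follow the usual 80/20 train/test convention with a further 10%
    of the training set retained for validation.
    """

    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


def split_data(X, y, spec: SplitSpec | None = None):
    """Split into ``(X_tr, y_tr), (X_val, y_val), (X_te, y_te)``.

    Deterministic given ``spec.seed``; stratified by class unless disabled.
    The three index sets are disjoint and cover every row.
    """
    spec = spec or SplitSpec()
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(y)
    if spec.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 3:
            raise StratificationError(
                f"smallest class has {counts.min()} members; need >= 3 for a "
                "stratified three-way split"
            )
    strat = y if spec.stratified else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=spec.test_fraction, stratify=strat, random_state=spec.seed
    )
    strat2 = y_tr if spec.stratified else None
    X_tr, X_val, y_tr, y_val = train_test_split(
        X_tr, y_tr,
        test_size=spec.validation_fraction_of_train,
        stratify=strat2,
        random_state=spec.seed + 1,
    )
    return (X_tr, y_tr), (X_val, y_val), (X_te, y_te)


def train(model, train_set, validation_set, config: dict | None = None):
    """Fit ``model`` on an explicit train/validation pair.

    ``config`` entries (epochs, batch_size, learning_rate, patience,
    random_state) override the estimator's parameters.  Returns
    ``(model, report)`` where the report carries per-epoch losses and
    accuracies plus the epoch count actually run.
    """
    if config:
        model.set_params(**{k: v for k, v in config.items()
                            if k in model.get_params()})
    X_tr, y_tr = train_set
    model.fit(X_tr, y_tr, validation_data=validation_set)
    report = {
        **model.history_,
        "epochs_run": model.n_iter_,
    }
    return model, report


def evaluate(model, X, y) -> dict:
    """Accuracy and per-class confusion counts on a labeled table."""
    if y is None:
        raise MissingLabelsError("evaluation requires class labels")
    y = np.asarray(y)
    pred = model.predict(X)
    cm = confusion_matrix(y, pred, labels=model.classes_)
    return {
        "accuracy": float(np.mean(pred == y)),
        "confusion": pd.DataFrame(cm, index=model.classes_, columns=model.classes_),
        "n": int(len(y)),
    }
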