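"""Splitting, optimization behavior, and evaluation identities."""
import numpy as np
import pytest
from sklearn.datasets import make_blobs

from mononet import MonoNetClassifier, evaluate, split_data, train
from mononet.errors import MissingLabelsError, StratificationError, TrainingDivergedError
from mononet.training import SplitSpec


@pytest.fixture(scope="module")
def blobs():
    return make_blobs(n_samples=500, centers=[[-3.0, 0.0], [3.0, 0.0]],
                      cluster_std=1.0, random_state=0)


def test_default_split_sizes():
    X = np.zeros((100, 3))
    y = np.repeat([0, 1], 50)
    (Xt, yt), (Xv, yv), (Xe, ye) = split_data(X, y, SplitSpec(seed=0))
    assert len(yt) == 72 and len(yv) == 8 and len(ye) == 20


def test_split_deterministic_and_covering():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(120, 2))
    y = rng.integers(0, 3, 120)
    spec = SplitSpec(seed=42)
    a = split_data(X, y, spec)
    b = split_data(X, y, spec)
    for (Xa, _), (Xb, _) in zip(a, b):
        np.testing.assert_array_equal(Xa, Xb)
    assert sum(len(part[1]) for part in a) == 120


def test_stratified_split_preserves_imbalanced_proportions():
    y = np.array([0] * 64 + [1] * 16)
    X = np.arange(80, dtype=float)[:, None]
    (_, yt), (_, yv), (_, ye) = split_data(X, y, SplitSpec(seed=0))
    # 80/20 class ratio preserved within one row per subset
    for part in (yt, yv, ye):
        frac = np.mean(part == 1)
        assert abs(frac * len(part) - 0.2 * len(part)) <= 1.0


def test_stratification_error_on_tiny_class():
    y = np.array([0] * 50 + [1] * 2)
    with pytest.raises(StratificationError):
        split_data(np.zeros((52, 2)), y, SplitSpec(seed=0))


def test_bad_fraction_rejected():
    with pytest.raises(ValueError):
        SplitSpec(test_fraction=1.2)


def test_separable_blobs_reach_high_accuracy(blobs):
    X, y = blobs
    tr, va, te = split_data(X, y, SplitSpec(seed=0))
    model = MonoNetClassifier(hidden_sizes=(8,), interpretable_size=4,
                              monotonic_sizes=(8,), epochs=80, random_state=0)
    model, report = train(model, tr, va)
    res = evaluate(model, *te)
    assert res["accuracy"] >= 0.95
    assert report["epochs_run"] == len(report["train_loss"])


def test_zero_epochs_returns_initial_parameters(blobs):
    X, y = blobs
    a = MonoNetClassifier(epochs=0, random_state=7).fit(X, y)
    b = MonoNetClassifier(epochs=0, random_state=7).fit(X, y)
    np.testing.assert_array_equal(a.predict_proba(X[:20]), b.predict_proba(X[:20]))
    assert a.history_["train_loss"] == []


def test_training_reproducible_given_seed(blobs):
    X, y = blobs
    runs = []
    for _ in range(2):
        m = MonoNetClassifier(hidden_sizes=(8,), interpretable_size=4,
                              monotonic_sizes=(8,), epochs=15, random_state=3)
        m.fit(X, y)
        runs.append((m.history_["train_loss"], m.predict_proba(X[:10])))
    assert runs[0][0] == runs[1][0]
    np.testing.assert_array_equal(runs[0][1], runs[1][1])


def test_divergence_reported_with_epoch(blobs):
    X, y = blobs
    m = MonoNetClassifier(hidden_sizes=(8,), interpretable_size=4,
                          monotonic_sizes=(8,), epochs=5, learning_rate=1e12,
                          validation_fraction=0, random_state=0)
    with np.errstate(all="ignore"), pytest.raises(TrainingDivergedError):
        m.fit(X, y)


def test_post_training_monotonicity_survives_optimization(blobs, rng):
    X, y = blobs
    m = MonoNetClassifier(hidden_sizes=(8,), interpretable_size=4,
                          monotonic_sizes=(8,), epochs=40, random_state=0).fit(X, y)
    assert m.check_monotonicity(X, n_base=50, rng=rng).passed


# ------------------------------------------------------------- evaluate
class _ConstantModel:
    classes_ = np.array([0, 1, 2, 3])

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


def test_evaluate_perfect_and_constant_predictors(trained_small):
    model, (tr, _, _) = trained_small
    X = tr[0][:10]
    res = evaluate(model, X, model.predict(X))
    assert res["accuracy"] == 1.0
    balanced = evaluate(_ConstantModel(), np.zeros((40, 2)), np.repeat([0, 1, 2, 3], 10))
    assert balanced["accuracy"] == 0.25


def test_accuracy_equals_confusion_trace(trained_small):
    model, (_, _, te) = trained_small
    res = evaluate(model, *te)
    cm = res["confusion"].to_numpy()
    assert cm.sum() == res["n"]
    assert res["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())


def test_evaluate_requires_labels(trained_small):
    model, (_, _, te) = trained_small
    with pytest.raises(MissingLabelsError):
        evaluate(model, te[0], None)
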