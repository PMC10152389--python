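"""Kolmogorov–Smirnov activation analysis against brute-force oracles."""
import numpy as np
import pytest
from scipy.stats import ks_2samp

from mononet import ecdf_value, global_importance, ks_score, neuron_marker_ks, rank_split
from mononet.errors import EmptySampleError, InvalidParameterError
from mononet.ks import KSMatrix
import pandas as pd


def _brute_force_ks(a, b):
    """O(n*m) evaluation of max |ECDF_a - ECDF_b| over all pooled points."""
    best = 0.0
    for x in list(a) + list(b):
        da = sum(1 for v in a if v <= x) / len(a)
        db = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(da - db))
    return best


# ------------------------------------------------------------------ ecdf
def test_ecdf_examples_and_boundaries():
    assert ecdf_value([1, 2, 3], 2) == pytest.approx(2 / 3)
    assert ecdf_value([1, 2, 3], 0.5) == 0.0
    assert ecdf_value([1, 2, 3], 3) == 1.0
    assert ecdf_value([1, 2, 3], 99) == 1.0


def test_ecdf_agrees_with_counting_loop(rng):
    sample = rng.integers(0, 10, 50).astype(float)
    for x in rng.uniform(-1, 11, 100):
        naive = sum(1 for v in sample if v <= x) / len(sample)
        assert ecdf_value(sample, x) == pytest.approx(naive)


def test_ecdf_empty_sample():
    with pytest.raises(EmptySampleError):
        ecdf_value([], 0.0)


# ------------------------------------------------------------------ ks
def test_ks_identical_and_disjoint():
    assert ks_score([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == 0.0
    assert ks_score([0.0, 0.0, 0.0], [1.0, 1.0, 1.0]) == 1.0


def test_ks_matches_brute_force_with_ties(rng):
    for _ in range(200):
        n, m = rng.integers(2, 30, size=2)
        # integer draws force ties within and across samples
        a = rng.integers(0, 8, n).astype(float)
        b = rng.integers(0, 8, m).astype(float)
        fast = ks_score(a, b)
        assert fast == pytest.approx(_brute_force_ks(a, b), abs=1e-12)
        assert fast == pytest.approx(ks_score(b, a), abs=1e-15)  # symmetry
        assert 0.0 <= fast <= 1.0


def test_ks_agrees_with_scipy(rng):
    for _ in range(50):
        a = rng.normal(size=rng.integers(5, 60))
        b = rng.normal(1.0, 1.5, size=rng.integers(5, 60))
        assert ks_score(a, b) == pytest.approx(ks_2samp(a, b).statistic, abs=1e-12)


# ------------------------------------------------------------ rank_split
def test_rank_split_examples():
    top, bottom = rank_split([5, 1, 4, 2, 3], 0.2)
    assert list(top) == [0] and list(bottom) == [1]
    top, bottom = rank_split(np.arange(10), 0.5)
    assert len(top) == len(bottom) == 5
    assert set(top) | set(bottom) == set(range(10))
    assert set(top).isdisjoint(bottom)


def test_rank_split_tie_break_deterministic(rng):
    acts = rng.integers(0, 3, 40).astype(float)  # heavy ties
    top1, bot1 = rank_split(acts, 0.25)
    perm = rng.permutation(40)
    top2, bot2 = rank_split(acts[perm], 0.25)
    # selected *values* identical regardless of row order
    np.testing.assert_array_equal(np.sort(acts[top1]), np.sort(acts[perm][top2]))
    np.testing.assert_array_equal(np.sort(acts[bot1]), np.sort(acts[perm][bot2]))
    assert acts[top1].min() >= acts[bot1].max()


@pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
def test_rank_split_bad_fraction(fraction):
    with pytest.raises(InvalidParameterError):
        rank_split(np.arange(10), fraction)


# --------------------------------------------------------- neuron x marker
class _FixedActivations:
    """Ranking driven by externally supplied activation values."""

    def __init__(self, H):
        self.H = H

    def interpretable_activations(self, X):
        return self.H[: len(X)]


def test_planted_marker_separation_detected(rng):
    n = 2000
    group = rng.random(n) < 0.5
    X = rng.standard_normal((n, 3))
    X[group, 0] += 5.0  # marker 0 high exactly where neuron 0 activates
    H = np.column_stack([group.astype(float) + 0.01 * rng.standard_normal(n),
                         rng.standard_normal(n)])
    ksm = neuron_marker_ks(_FixedActivations(H), X)
    assert ksm.scores.iloc[0, 0] > 0.9
    assert ksm.scores.iloc[0, 1] < 0.2  # independent noise marker
    assert ksm.directions.iloc[0, 0] == 1.0


def test_null_table_scores_stay_below_simulated_null(rng):
    n = 2000
    X = rng.standard_normal((n, 10))
    H = rng.standard_normal((n, 16))  # activations independent of markers
    ksm = neuron_marker_ks(_FixedActivations(H), X)
    k = int(0.2 * n)
    null = np.array([ks_score(rng.standard_normal(k), rng.standard_normal(k))
                     for _ in range(300)])
    assert ksm.scores.to_numpy().max() <= np.quantile(null, 0.99) + 0.05


def test_constant_neuron_flagged(rng):
    H = np.column_stack([np.ones(50), rng.standard_normal(50)])
    ksm = neuron_marker_ks(_FixedActivations(H), rng.standard_normal((50, 2)))
    assert ksm.constant_neurons == ["neuron_0"]


def test_fraction_robustness_on_trained_model(trained_small, cytof_small):
    """Higher thresholds lower the KS score but keep strong markers on top."""
    model, _ = trained_small
    X = cytof_small[0]
    lo = neuron_marker_ks(model, X, fraction=0.1)
    hi = neuron_marker_ks(model, X, fraction=0.3)
    for neuron in lo.neurons:
        best = lo.top_markers(neuron, 1)[0]
        assert hi.scores.loc[neuron, best] <= lo.scores.loc[neuron, best] + 0.05
        assert best in hi.top_markers(neuron, 4)


# ------------------------------------------------------- global importance
def test_global_importance_trivial_cases():
    flat = KSMatrix(
        scores=pd.DataFrame(0.5, index=["n0", "n1"], columns=["a", "b"]),
        directions=pd.DataFrame(1.0, index=["n0", "n1"], columns=["a", "b"]),
        fraction=0.2,
    )
    assert (global_importance(flat) == 0.5).all()
    single = KSMatrix(
        scores=pd.DataFrame([[0.1, 0.9]], index=["n0"], columns=["a", "b"]),
        directions=pd.DataFrame([[1.0, 1.0]], index=["n0"], columns=["a", "b"]),
        fraction=0.2,
    )
    assert list(global_importance(single)) == [0.1, 0.9]
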