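"""The structural monotonicity guarantee and its sign/strength descriptor."""
import numpy as np
import pytest

from mononet import MonoNetClassifier, sign_strength_matrix, sweep_monotonicity
from mononet._net import MonotonicHead
from mononet.errors import DegenerateRescalingError, DimensionError
from mononet.monotonic import monotonic_layer_forward

TRANSFORMS = ["exponential", "square", "shifted_tanh"]


def _random_head(rng, p=6, q=5, depth=2, transform="exponential",
                 activation="tanh", residual=False):
    return MonotonicHead(p, tuple([7] * depth), q, transform=transform,
                         activation=activation, residual=residual,
                         rng=rng)


# --------------------------------------------------------- single layer
def test_layer_forward_all_ones_weights_sum_inputs():
    out = monotonic_layer_forward(
        np.array([1.0, 2.0, 3.0]), np.zeros((2, 3)), np.zeros(2),
        transform="exponential", activation="identity",
    )
    np.testing.assert_allclose(out, [6.0, 6.0])


@pytest.mark.parametrize("transform", TRANSFORMS)
def test_layer_forward_never_decreases_in_any_coordinate(rng, transform):
    W = rng.normal(size=(4, 5))
    b = rng.normal(size=4)
    for _ in range(100):
        h = rng.normal(size=5)
        i = rng.integers(5)
        delta = rng.uniform(0.01, 2.0)
        h2 = h.copy()
        h2[i] += delta
        lo = monotonic_layer_forward(h, W, b, transform)
        hi = monotonic_layer_forward(h2, W, b, transform)
        assert np.all(hi >= lo - 1e-12)


def test_layer_forward_shape_mismatch():
    with pytest.raises(DimensionError):
        monotonic_layer_forward(np.ones(4), np.zeros((2, 3)), np.zeros(2))


# --------------------------------------------------------- stacked heads
@pytest.mark.parametrize("depth", [1, 2, 3, 4])
@pytest.mark.parametrize("transform", TRANSFORMS)
def test_sweep_passes_at_all_depths_and_transforms(rng, depth, transform):
    head = _random_head(rng, depth=depth, transform=transform)
    H = rng.normal(size=(150, 6))
    res = sweep_monotonicity(head, H, n_base=30, rng=rng)
    assert res.passed, f"violations={res.n_violations} worst={res.worst_violation}"


def test_sweep_passes_with_relu_and_residual(rng):
    head = _random_head(rng, depth=2, activation="relu", residual=True)
    H = rng.normal(size=(100, 6))
    assert sweep_monotonicity(head, H, n_base=30, rng=rng).passed


# --------------------------------------------------------- forward trace
def test_hand_computed_identity_head():
    """Zero raw weights + exponential = all-ones weights; identity activation
    turns the head into iterated summation: h=(1,2,3) -> (6,6) -> (12,12)."""
    head = MonotonicHead(3, (2,), 2, activation="identity",
                         rng=np.random.default_rng(0))
    for k in ("V0", "V1"):
        head.params[k][...] = 0.0
    for k in ("c0", "c1"):
        head.params[k][...] = 0.0
    head.params["alpha"][...] = 1.0
    head.params["beta"][...] = 1.0
    trace, _ = head.forward(np.array([[1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(dict(trace)["monotonic_1"], [[6.0, 6.0]])
    np.testing.assert_allclose(dict(trace)["output"], [[12.0, 12.0]])


def test_forward_trace_shapes_and_probability_rows(trained_small):
    model, (tr, _, _) = trained_small
    X = tr[0][:50]
    trace = model.forward_trace(X)
    assert trace["interpretable"].shape == (50, 8)
    assert trace["monotonic_2"].shape == (50, 32)
    assert trace["output"].shape == (50, 8)
    np.testing.assert_allclose(trace["probabilities"].sum(axis=1), 1.0, atol=1e-6)


def test_forward_rejects_wrong_width(trained_small):
    model, _ = trained_small
    with pytest.raises(DimensionError):
        model.forward_trace(np.zeros((3, 7)))


# --------------------------------------------------------- sign/strength
def test_sign_strength_identity_and_arithmetic():
    ones = sign_strength_matrix(np.ones(2), np.ones(2))
    np.testing.assert_allclose(ones.to_numpy(), np.ones((2, 2)))
    single = sign_strength_matrix(np.array([2.0]), np.array([-4.0]))
    np.testing.assert_allclose(single.to_numpy(), [[-0.125]])


def test_sign_strength_degenerate_pair_named():
    with pytest.raises(DegenerateRescalingError, match="alpha_1 \\* beta_0"):
        sign_strength_matrix(np.array([1.0, 1e-15]), np.array([1.0]))


@pytest.mark.parametrize("transform", TRANSFORMS)
def test_sign_strength_signs_match_empirical_slopes(rng, transform):
    head = _random_head(rng, p=5, q=4, depth=2, transform=transform)
    signs = np.sign(np.outer(head.params["alpha"], head.params["beta"]))
    H = rng.normal(size=(50, 5))
    for i in range(5):
        delta = np.zeros(5)
        delta[i] = 1e-3
        slope = head.logits(H + delta) - head.logits(H)
        # empirical slope of logit j w.r.t. neuron i never opposes sign(a_i b_j)
        assert np.all(slope * signs[i] >= -1e-9)


def test_trained_model_sign_strength_consistent_with_sweeps(trained_small, rng):
    model, (tr, _, _) = trained_small
    res = model.check_monotonicity(tr[0][:1000], n_base=50, rng=rng)
    assert res.passed
    ss = model.sign_strength_matrix()
    np.testing.assert_array_equal(
        np.sign(ss.to_numpy()), np.sign(np.outer(model.alpha_, model.beta_))
    )
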