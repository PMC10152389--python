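"""Synthetic generators: determinism and the planted statistical structure."""
import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from mononet import make_monotone_task, make_motif_images, make_signatures, sample_cells
from mononet.errors import InvalidParameterError
from mononet.synthetic import HIGH, IRRELEVANT, MOTIFS, locate_motif


# ------------------------------------------------------------- signatures
def test_signature_construction_guarantees():
    sig = make_signatures(8, 13, seed=0)
    states = sig.states
    assert states.shape == (8, 13)
    assert all(len(sig.high_markers(p)) >= 1 for p in sig.populations)
    assert len(sig.decoy_markers) >= 1
    for m in sig.decoy_markers:
        assert (states[m] == IRRELEVANT).all()
    shared_counts = (states == HIGH).sum(axis=0)
    assert (shared_counts >= 2).any()  # at least one shared lineage marker
    assert sig.prevalences.sum() == pytest.approx(1.0)
    assert not states.duplicated().any()  # distinct population identities


def test_signatures_deterministic():
    a = make_signatures(8, 13, seed=3)
    b = make_signatures(8, 13, seed=3)
    assert a.states.equals(b.states)
    np.testing.assert_array_equal(a.prevalences, b.prevalences)


def test_signatures_reject_tiny_counts():
    with pytest.raises(InvalidParameterError):
        make_signatures(1, 13)


# ------------------------------------------------------------------ cells
def test_high_marker_population_means_within_clt_bound(cytof_sig):
    X, y = sample_cells(cytof_sig, 20000, seed=0)
    for p in cytof_sig.populations:
        cells = X[(y == p).to_numpy()]
        for m in cytof_sig.high_markers(p):
            bound = 3.0 * cytof_sig.sigma / np.sqrt(len(cells))
            assert abs(cells[m].mean() - cytof_sig.mu_high) < bound * 1.5


def test_decoy_marker_carries_no_class_signal(cytof_sig):
    X, y = sample_cells(cytof_sig, 10000, seed=0)
    m = cytof_sig.decoy_markers[0]
    groups = [X[(y == p).to_numpy()][m].to_numpy() for p in cytof_sig.populations]
    grand = X[m].mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (len(groups) - 1)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups) / (len(X) - len(groups))
    assert between / within < 3.0  # one-way variance ratio ~ 1


def test_shared_marker_pooled_distribution_is_bimodal(cytof_sig):
    """A marker high in several populations mixes two Gaussian modes; a
    two-component mixture must beat one component on the pooled sample but
    not on a single-population sample."""
    X, y = sample_cells(cytof_sig, 8000, seed=0)
    shared = cytof_sig.meta["shared"][0]
    pooled = X[shared].to_numpy().reshape(-1, 1)
    bic1 = GaussianMixture(1, random_state=0).fit(pooled).bic(pooled)
    bic2 = GaussianMixture(2, random_state=0).fit(pooled).bic(pooled)
    assert bic2 < bic1
    single_pop = pooled[(y == cytof_sig.populations[0]).to_numpy()]
    sb1 = GaussianMixture(1, random_state=0).fit(single_pop).bic(single_pop)
    sb2 = GaussianMixture(2, random_state=0).fit(single_pop).bic(single_pop)
    assert sb1 <= sb2 + 10.0  # one component suffices within a population


def test_cells_deterministic(cytof_sig):
    Xa, ya = sample_cells(cytof_sig, 500, seed=9)
    Xb, yb = sample_cells(cytof_sig, 500, seed=9)
    assert Xa.equals(Xb) and ya.equals(yb)


# ---------------------------------------------------------- monotone task
def test_monotone_task_labels_follow_generating_rule():
    X, y, latents = make_monotone_task(500, seed=0)
    g1, g2 = latents[:, 0], latents[:, 1]
    np.testing.assert_allclose(g1, X[:, 0] * X[:, 1])
    np.testing.assert_allclose(g2, np.sin(X[:, 2]) + X[:, 3])
    logit = (g1 + 0.25 * g1**3) - np.exp(g2)
    np.testing.assert_array_equal(y, (logit > 0).astype(int))  # Bayes acc 1.0


# ------------------------------------------------------------------ images
def test_motif_images_deterministic_and_located():
    a = make_motif_images(50, image_size=16, seed=4)
    b = make_motif_images(50, image_size=16, seed=4)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[2], b[2])


def test_template_matcher_finds_noise_free_motifs():
    imgs, labels, boxes = make_motif_images(60, image_size=16, seed=1, noise=0.0)
    for img, lab, (r, c) in zip(imgs, labels, boxes):
        assert locate_motif(img, MOTIFS[int(lab)]) == (r, c)


def test_each_image_contains_its_motif_exactly_once():
    imgs, labels, boxes = make_motif_images(30, image_size=16, seed=1, noise=0.0,
                                            amplitude=1.0)
    for img, lab, (r, c) in zip(imgs, labels, boxes):
        motif = MOTIFS[int(lab)]
        np.testing.assert_array_equal(img[r:r + 3, c:c + 3], motif)
        assert img.sum() == pytest.approx(motif.sum())  # nothing else planted
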