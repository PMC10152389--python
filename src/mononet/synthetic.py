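"""Synthetic data generators for every analysis stage.

Three families of fixtures:

* a CyTOF-like marker table: cell populations defined by high/low marker
  signatures with per-marker Gaussian noise on an arcsinh-like scale,
  including markers shared between populations (which makes their pooled
  distribution bimodal, as in real lineage markers) and decoy markers that
  carry no population signal at all;
* a latent-monotone classification task whose labels are, by construction, a
  monotone function of two hidden nonlinear features of the input;
* small grayscale images where each class is defined by a distinct 3x3 motif
  stamped at a random position over background noise.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "SignatureMatrix",
    "make_signatures",
    "sample_cells",
    "make_monotone_task",
    "make_motif_images",
    "MOTIFS",
]

HIGH, LOW, IRRELEVANT = "high", "low", "irrelevant"


@dataclass
class SignatureMatrix:
    """Population x marker signature table driving the CyTOF-like sampler.

    ``states`` entries are ``"high"``, ``"low"`` or ``"irrelevant"``;
    irrelevant markers are sampled exactly like low ones but are never part
    of any population's identity, and markers irrelevant in *every*
    population are decoys.
    """

    states: pd.DataFrame  # populations x markers, entries in {high, low, irrelevant}
    prevalences: np.ndarray
    mu_high: float = 3.0
    mu_low: float = 0.0
    sigma: float = 1.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.states.index)

    @property
    def markers(self) -> list[str]:
        return list(self.states.columns)

    @property
    def decoy_markers(self) -> list[str]:
        return [m for m in self.markers if (self.states[m] == IRRELEVANT).all()]

    def high_markers(self, population: str) -> list[str]:
        row = self.states.loc[population]
        return [m for m in self.markers if row[m] == HIGH]


def make_signatures(
    n_populations: int = 8,
    n_markers: int = 13,
    seed: int | None = 0,
    n_decoys: int = 2,
) -> SignatureMatrix:
    """Build a random signature matrix with guaranteed structure.

    Guarantees, by construction: every population has at least one high
    marker; at least one marker is high in two or more populations (a shared
    "lineage" marker); when ``n_markers >= 5`` at least one decoy column is
    entirely irrelevant.  Population prevalences are drawn from a Dirichlet
    so the mixture is imbalanced, like real immune subpopulation frequencies.
    """
    if n_populations < 2 or n_markers < 2:
        raise InvalidParameterError("need at least 2 populations and 2 markers")
    rng = np.random.default_rng(seed)
    markers = [f"M{i + 1:02d}" for i in range(n_markers)]
    pops = [f"pop_{chr(ord('A') + i)}" for i in range(n_populations)]
    n_decoys = min(n_decoys, n_markers - 2) if n_markers >= 5 else 0
    decoys = markers[n_markers - n_decoys:]
    usable = markers[: n_markers - n_decoys]

    states = pd.DataFrame(IRRELEVANT, index=pops, columns=markers)
    # shared lineage marker: high in the first two populations
    shared = usable[0]
    states.loc[pops[0], shared] = HIGH
    states.loc[pops[1], shared] = HIGH
    # every population gets 2-4 high markers and 1-2 explicit low markers
    for p in pops:
        k_high = int(rng.integers(2, min(5, len(usable)) + 1)) - (
            1 if states.loc[p].eq(HIGH).any() else 0
        )
        candidates = [m for m in usable if states.loc[p, m] != HIGH]
        chosen = rng.choice(candidates, size=min(k_high, len(candidates)), replace=False)
        for m in chosen:
            states.loc[p, m] = HIGH
        remaining = [m for m in usable if states.loc[p, m] == IRRELEVANT]
        k_low = min(int(rng.integers(1, 3)), len(remaining))
        for m in rng.choice(remaining, size=k_low, replace=False):
            states.loc[p, m] = LOW
    # ensure distinct signatures: flip a marker for any duplicated row
    for _ in range(10 * n_populations):
        dup = states.duplicated(keep="first")
        if not dup.any():
            break
        p = states.index[dup.argmax()]
        flip = [m for m in usable if states.loc[p, m] != HIGH] or usable
        m = rng.choice(flip)
        states.loc[p, m] = HIGH if states.loc[p, m] != HIGH else LOW

    prevalences = rng.dirichlet(np.full(n_populations, 2.0))
    prevalences = np.clip(prevalences, 0.02, None)
    prevalences = prevalences / prevalences.sum()
    return SignatureMatrix(
        states=states,
        prevalences=prevalences,
        seed=seed,
        meta={"n_decoys": n_decoys, "decoys": decoys, "shared": [shared]},
    )


def sample_cells(
    signatures: SignatureMatrix,
    n_cells: int = 20_000,
    seed: int | None = 0,
):
    """Sample a labeled marker table from a signature matrix.

    Marker values are ``N(mu_high, sigma)`` where the population's signature
    is high and ``N(mu_low, sigma)`` otherwise, mimicking arcsinh-transformed
    cytometry intensities.  Returns ``(X, labels)`` where ``X`` is a cells x
    markers DataFrame and ``labels`` a population-name Series.
    """
    if n_cells < len(signatures.populations):
        raise InvalidParameterError("n_cells must be at least the number of populations")
    rng = np.random.default_rng(seed)
    pop_idx = rng.choice(len(signatures.populations), size=n_cells, p=signatures.prevalences)
    means = np.where(
        signatures.states.to_numpy() == HIGH, signatures.mu_high, signatures.mu_low
    )  # populations x markers
    X = means[pop_idx] + rng.normal(0.0, signatures.sigma, size=(n_cells, len(signatures.markers)))
    labels = pd.Series(
        np.asarray(signatures.populations, dtype=object)[pop_idx], name="population"
    )
    return pd.DataFrame(X, columns=signatures.markers), labels


def make_monotone_task(n: int = 2000, seed: int | None = 0, noise: float = 0.0):
    """Binary task whose label is a monotone function of two latent features.

    Inputs ``x in R^4`` are uniform on [-2, 2]; the latents are
    ``g1 = x1 * x2`` and ``g2 = sin(x3) + x4``; the class logit is
    ``f1(g1) - f2(g2)`` with ``f1(t) = t + t^3/4`` and ``f2(t) = e^t`` (both
    strictly increasing), so the label depends on the input only through a
    representation that is monotonically related to the output.  Returns
    ``(X, y, latents)``; in the noise-free variant the generating rule
    labels its own data perfectly.
    """
    if n < 100:
        raise InvalidParameterError("n must be >= 100")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-2.0, 2.0, size=(n, 4))
    g1 = X[:, 0] * X[:, 1]
    g2 = np.sin(X[:, 2]) + X[:, 3]
    logit = (g1 + 0.25 * g1**3) - np.exp(g2)
    if noise:
        logit = logit + rng.normal(0.0, noise, size=n)
    y = (logit > 0).astype(int)
    return X, y, np.column_stack([g1, g2])


MOTIFS = {
    0: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=float),  # plus
    1: np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=float),  # cross
    2: np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float),  # ring
}


def make_motif_images(
    n: int = 3000,
    image_size: int = 28,
    seed: int | None = 0,
    noise: float = 0.5,
    amplitude: float = 3.0,
    n_classes: int = 3,
):
    """Labeled image set where each class plants a distinct 3x3 motif.

    Returns ``(images, labels, boxes)``: images of shape (n, H, W), integer
    labels, and (row, col) top-left corners of each planted motif for
    localization tests.  Background is N(0, noise); the motif pattern is
    added with the given amplitude at a uniformly random position.
    """
    if n_classes > len(MOTIFS):
        raise InvalidParameterError(f"at most {len(MOTIFS)} motif classes available")
    if image_size < 3:
        raise InvalidParameterError("motif does not fit in the image")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n)
    images = rng.normal(0.0, noise, size=(n, image_size, image_size))
    boxes = np.empty((n, 2), dtype=int)
    span = image_size - 3 + 1
    for t in range(n):
        r, c = rng.integers(0, span, size=2)
        images[t, r:r + 3, c:c + 3] += amplitude * MOTIFS[int(labels[t])]
        boxes[t] = (r, c)
    return images, labels, boxes


def locate_motif(image: np.ndarray, motif: np.ndarray) -> tuple[int, int]:
    """Brute-force template matcher: top-left corner maximizing correlation."""
    h, w = motif.shape
    H, W = image.shape
    best, arg = -np.inf, (0, 0)
    for r in range(H - h + 1):
        for c in range(W - w + 1):
            s = float((image[r:r + h, c:c + w] * motif).sum())
            if s > best:
                best, arg = s, (r, c)
    return arg
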