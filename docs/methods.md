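# Methods

## Model

A MonoNet for a `d`-marker, `q`-class problem is the composition

```
x ─ unconstrained block ─ h ─ α⊙ ─ monotonic stack ─ ỹ ─ β⊙ ─ y (logits)
```

* **Unconstrained block**: dense layers of sizes `hidden_sizes` followed by
  the interpretable layer of width `interpretable_size`, all with the shared
  activation (default tanh). Nothing is constrained here; it is interpreted
  post hoc.
* **Monotonic stack**: dense layers whose stored raw matrices `V` enter the
  forward pass as `t(V)` with `t` one of `exp` (default, strictly positive),
  `V²`, or `tanh(V)+1`. Hidden monotonic layers use the shared activation;
  the final layer of the stack, producing `ỹ`, is linear. Since every
  effective weight is ≥ 0 and every offered activation is non-decreasing,
  each component of `ỹ` is non-decreasing in each component of `h̃`, and
  stacking preserves this.
* **Rescalings**: `h̃ = α⊙h`, `y = β⊙ỹ` with `α, β` trainable. The
  direction of logit `j` in neuron `i` is `sign(αᵢβⱼ)`; the matrix
  `1/(αᵢβⱼ)` is exposed as the sign/strength descriptor of each pair. The
  network maps `h` to `y`, and we use `1/(αᵢβⱼ)` purely as that pair's
  direction/strength label without assigning it a derivative
  interpretation in either direction.

Class probabilities are `softmax(y)` and exist for training and
`predict_proba` only; the monotonic contract is stated and checked on the
pre-softmax logits, because softmax mixes classes and would couple the
per-class directions.

The default architecture (13 → 16 → 16 → 8 → 32 → 32 → q) is the
mass-cytometry case-study configuration this package is built around: 13
markers, three unconstrained layers of 16/16/8 with the 8-unit layer
interpretable, and two 32-unit monotonic layers.

**α/β initialization.** The reference construction leaves open whether α, β
are learned; here they are trainable, initialized from a standard normal
with any draw inside (−10⁻³, 10⁻³) resampled, and clamped away from zero
(|·| ≥ 10⁻¹²) after every optimizer step. Letting the signs be learned is
what allows arbitrary per-pair monotone directions to emerge from data; the
resampling band and clamp keep `1/(αᵢβⱼ)` well defined. Raw monotonic
weights are initialized so the *transformed* weights start near `1/fan_in`
(e.g. `V ~ N(log(1/fan_in), 0.5)` under `exp`), which puts the positive
weight stack in a reasonable operating range at step 0. Biases are
unconstrained everywhere (they do not affect monotonicity).

## Training

Softmax cross-entropy minimized with Adam, implemented in numpy with
analytic gradients (the transform's chain-rule factor is `t′(V)`). Defaults:
learning rate 1e−3, batch 256, up to 150 epochs, early stopping on
validation accuracy with patience 10, restoring the best-validation
parameters. The convolutional variant defaults to learning rate 3e−3, up to
80 epochs, patience 20 — the conv-plus-top-k front end converges noticeably
slower at 1e−3. None of these choices affects the monotonic guarantee,
which is architectural; training determinism holds for a fixed seed and
thread count.

Data splitting follows the 80/20 train/test convention with 10% of the
training set retained for validation, stratified by class (the synthetic
populations are imbalanced, and unstratified splits are fragile for rare
classes); splits are deterministic given the seed.

## The monotonicity sweep oracle

The executable form of the guarantee: for each interpretable neuron, base
points are drawn uniformly from the coordinate-wise empirical range of a
reference activation set, the neuron's coordinate is swept over a 21-point
grid spanning its range, and every logit trajectory must be non-decreasing
(direction `sign(αᵢβⱼ) = +1`) or non-increasing (−1) up to a tolerance of
1e−7 — the tolerance absorbs float round-off in long chains of matmuls,
not any model slack. Defaults: 100 base points per neuron, every
(neuron, logit) pair. The suite runs this at monotonic depths 1–4, for all
three transforms, for tanh and ReLU, with and without the residual
connection, on untrained and trained networks.

## KS activation analysis

For each interpretable neuron, cells are ranked by activation and the top
and bottom `fraction` (default 0.2) are selected, both of size
`floor(fraction·n)`; ties are resolved by a stable sort on
(activation, original index) so the split is a deterministic function of
the data. Each marker's two subsets are compared with the two-sample KS
statistic evaluated at all pooled sample points with the ≤ convention —
exact under ties, and verified in tests against both a quadratic
brute-force scan and `scipy.stats.ks_2samp`. The direction sign is the sign
of the median difference (top minus bottom); medians rather than means
because shared lineage markers make the subset distributions bimodal. No
p-values are attached: the statistic is used as a separation score, not a
test. Global per-marker importance is the mean score across neurons
(absolute values first when the same reduction is applied to Shapley
matrices). Constant-activation neurons still get a deterministic tie-broken
split but are flagged in the result.

A robustness view is part of the API (`fraction` is a parameter): raising
the fraction lowers scores, but strongly separated markers keep their
within-neuron rank — the suite checks both on trained models.

## Shapley attribution

The value function is the vector of interpretable-neuron activations;
absent features are replaced by a single background vector, the training
mean. A single-vector background keeps the exact oracle cheap and makes
"efficiency" read `Σφ = h(x) − h(mean cell)` per neuron.

* **Exact** (default for ≤ 15 features): full 2ⁿ coalition enumeration with
  the classic permutation weights — 8192 evaluations per cell for the
  13-marker panel, all neurons in one vectorized pass. Efficiency holds to
  float precision on every explained cell.
* **KernelSHAP** (larger panels): coalition sizes whose complete
  enumeration fits their share of the sample budget are enumerated with
  the analytic kernel weight `(n−1)/(C(n,s)·s(n−s))`; the remaining budget
  is sampled from the kernel distribution over the leftover sizes. The
  weighted least-squares system eliminates one coefficient to enforce
  efficiency exactly and is deterministic given the seed. When the budget
  covers all coalitions the estimate coincides with exact enumeration up
  to regression round-off.

Per-neuron matrices aggregate `n_explained` (default 500) seeded sample
cells by the mean of per-cell attributions — the simplest aggregation
consistent with treating the matrix like the KS matrix.

## Information flow

`ami_profile` clusters every recorded layer's activations (input,
unconstrained layers, interpretable, pre-monotonic, monotonic layers,
output logits) with K-means and BIRCH, both at library defaults with the
cluster count equal to the number of classes — the count that makes AMI
against class labels most interpretable — and scores each clustering
against the model's predicted and the true labels with adjusted mutual
information under the permutation-model expectation (arithmetic mean
normalization). Profiles are computed on held-out data to avoid
memorization effects; zero-variance layers are reported as AMI 0 and
flagged. `activation_summary` reports per-layer, per-class mean and
mean-absolute activations; the "absolute-activation rise" check compares
the *output* layer — the last positive-weight layer of the monotonic stack
— against the interpretable layer, since the hidden monotonic layers are
tanh-bounded and only the final linear positive-weight layer can express
the unbounded separation the stack builds.

## Convolutional variant

One unconstrained convolutional layer (default 32 filters, 3×3, stride 1,
no padding; a second conv layer is deliberately out of scope), the shared
activation, then per-feature-map top-k extraction (default k = 4): the
`n_filters·k` values, sorted within each map, form the interpretable layer,
and each carries its spatial argmax so interpretations localize. The head
is the tabular one plus a monotonic residual connection — a single
positive-weight linear layer from `h̃` straight to `ỹ`, sharing α and β
with the block; a sum of two maps monotone in the same directions is
monotone, so the contract is unchanged. Top-k tie-breaking is row-major
and deterministic in the public `topk_pool`; the batched training path uses
argpartition and resolves boundary ties arbitrarily, which is immaterial
for continuous activations. Receptive-field rectangles are
`[r, r+ks−1] × [c, c+ks−1]` for stride 1, checked by planting a delta
image. The "class-defining filter" for a class is the filter whose top-1
unit has the largest |sign/strength| entry toward that class.

## Synthetic data

The generator emulates the structure the analyses consume, not the
instrument:

* **CyTOF-like tables**: populations defined by high/low marker signatures;
  marker values `N(3, 1)` where high and `N(0, 1)` otherwise, i.e. Gaussian
  noise on an arcsinh-like scale. Guaranteed by construction: every
  population has ≥ 1 high marker, at least one marker is high in ≥ 2
  populations (shared lineage marker — its pooled distribution is bimodal,
  which the suite verifies by a 2- vs 1-component Gaussian-mixture BIC
  comparison), and ≥ 2 decoy markers carry no population signal at all.
  Prevalences are Dirichlet-drawn and imbalanced. Defaults: 8 populations,
  13 markers, 20 000 cells — a panel of the real case study's marker width
  at a desk-scale population count.
* **Monotone-latent task**: labels are a deterministic monotone function of
  two nonlinear latents (`g₁ = x₁x₂`, `g₂ = sin x₃ + x₄`), the setting the
  architecture is designed for; the generator returns the latents for
  recovery tests.
* **Motif images**: each class stamps a distinct 3×3 motif at a random
  position on Gaussian background noise; planted boxes are returned for
  localization scoring, and a brute-force template matcher serves as the
  locator oracle.

What the generator does **not** emulate: spillover, debris/doublets,
heavy-tailed or zero-inflated intensities, correlated marker noise within a
population, batch effects. Passing tests therefore demonstrate that the
machinery recovers planted structure under clean Gaussian conditions — not
that it is robust to instrument artifacts.

One consequence observed honestly: at these defaults the task is nearly
Bayes-separable (Bayes accuracy ≈ 0.988), so *every* layer of a trained
network clusters to high AMI and the rise of AMI from the interpretable
layer to the output layer — reported on the real 20-class data the
architecture was introduced on — does not reliably emerge: output-minus-
interpretable AMI differences here sit within ±0.03 and vary in sign across
seeds and clusterers. The acceptance suite asserts the rise anyway (and
currently fails it), and `scripts/acceptance.py` reports the measured
minimum difference rather than hiding it.

## Numerical and engineering choices

Float64 throughout; degenerate sign/strength pairs (|αᵢβⱼ| < 10⁻¹²) raise
an error naming the pair; checkpoints store full-precision arrays next to a
JSON manifest with a SHA-256 checksum, so load(save(m)) reproduces logits
bit-exactly and corruption is detected. Problem sizes used by the test and
acceptance runs (20 000 cells, 3000 images, 500 explained cells, 500-draw
null simulations, 100 base points per sweep) are the package's default
study sizes; they complete in minutes on one CPU.

## Known limitations

* Monotonicity is guaranteed w.r.t. the interpretable layer, not the input
  markers; the unconstrained block is interpreted only post hoc.
* The KS analysis is univariate per marker and blind to joint effects.
* KernelSHAP inherits the single-background simplification; a distributional
  background would change attribution magnitudes.
* Recurrent/transformer variants and multi-layer monotonic convolutions are
  out of scope; the image variant handles small single-channel images.
* No FCS parsing: tables are expected as delimited text exported upstream.
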