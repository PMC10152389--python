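# mononet

Interpretable-by-construction monotonic neural networks for single-cell
proteomics classification — with the complete interpretation workflow:
Kolmogorov–Smirnov activation analysis, Shapley attribution, the monotone
sign/strength matrix, and layer-wise information-flow profiling.

## The problem

Mass cytometry (CyTOF) measures the abundance of a panel of surface markers
in single cells; classifying cells into immune populations from these
markers is routine, but practitioners need to know *why* a classifier calls
a cell an immature B cell, not just that it does. Fully unconstrained neural
networks are accurate but opaque; fully transparent models (shallow trees,
risk scores) give up accuracy on harder panels.

A **MonoNet** is a compromise enforced by architecture. The network is an
ordinary MLP up to a chosen *interpretable layer* `h`; from `h` to the
output it is built only from layers whose weights pass through a positive
element-wise transform,

```
h(k+1) = σ(exp(W(k)) h(k) + b(k)),
```

so every output logit is **monotone** in every interpretable neuron — for
any parameter values, before or after training. Because ∂h(k+1)/∂h(k) =
σ′(·)·exp(W) ≥ 0 and compositions of non-decreasing maps stay
non-decreasing, the guarantee is structural, not penalized. Component-wise
rescalings bracket the monotonic stack,

```
h̃ = α ⊙ h,      y = β ⊙ ỹ,
```

so each (neuron i, class j) pair may be increasing or decreasing: the
direction is `sign(αᵢβⱼ)` and the quantity `1/(αᵢβⱼ)` is reported as the
*sign/strength matrix*. Interpretation is then two-step: (1) explain what
each interpretable neuron detects in terms of the input markers — by
ranking cells on the neuron's activation and comparing marker distributions
of the top vs bottom 20% with the two-sample KS score
`D = max |ECDF_top − ECDF_bottom|`, and by Shapley attribution of markers to
neuron activations; (2) read the neuron → class direction off the
sign/strength matrix. A convolutional variant (`MonoCNNClassifier`) uses one
unconstrained conv layer, keeps each filter's top-k activations (with their
image locations) as the interpretable layer, and adds a monotonic residual
connection, so "region R provides evidence for/against class c" statements
come with the same guarantee.

All estimators are scikit-learn compatible (`fit`/`predict`/`predict_proba`,
`get_params`, fitted attributes like `alpha_`, `classes_`) and the networks
are implemented in pure numpy (analytic gradients, Adam), so the package has
no deep-learning framework dependency.

## Worked example

```python
from mononet import (MonoNetClassifier, evaluate, global_importance,
                     make_signatures, neuron_marker_ks, sample_cells, split_data)
from mononet.training import SplitSpec

signatures = make_signatures(n_populations=8, n_markers=13, seed=0)
X, y = sample_cells(signatures, n_cells=20_000, seed=0)
train, val, test = split_data(X.to_numpy(), y.to_numpy(), SplitSpec(seed=0))

model = MonoNetClassifier(random_state=0)  # 13 -> 16 -> 16 -> 8 -> 32 -> 32 -> 8
model.fit(*train, validation_data=val)
print(f"test accuracy: {evaluate(model, *test)['accuracy']:.3f}")

ks = neuron_marker_ks(model, X, fraction=0.2)
print("neuron_0 top markers by KS:", ks.top_markers("neuron_0", 4))
print(global_importance(ks).sort_values().head(3).round(3).to_string())

ss = model.sign_strength_matrix(neuron_names=ks.neurons)
cls = ss.columns[0]
print(f"strongest positive neuron for {cls}: {ss[cls].idxmax()}",
      f"(1/(alpha*beta) = {ss[cls].max():.2f})")
print("that population's true high markers:", signatures.high_markers(cls))
```

prints

```
test accuracy: 0.980
neuron_0 top markers by KS: ['M08', 'M02', 'M06', 'M09']
M13    0.029
M12    0.030
M05    0.193
strongest positive neuron for pop_A: neuron_2 (1/(alpha*beta) = 0.86)
that population's true high markers: ['M01', 'M04', 'M05', 'M06', 'M09']
```

Read it as: the model classifies the synthetic panel at 98% test accuracy;
neuron 0 specializes in markers M08/M02/M06/M09 (high KS separation between
its top- and bottom-activating cells); the two decoy markers M13 and M12 —
which carry no population signal by construction — receive the lowest
global importance; and population `pop_A`'s logit increases most directly
with neuron 2, whose top markers overlap `pop_A`'s true signature. The same
workflow runs from the shell:

```
mononet synth cytof --out cells.csv --seed 0
mononet train --data cells.csv --out run/ --seed 0
mononet report --model run/ --data cells.csv --out report/
```

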