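"""Optional matplotlib views of the interpretation artifacts."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .ks import rank_split


def plot_marker_violins(model, X, neuron_index: int, fraction: float = 0.2, ax=None):
    """Side-by-side marker distributions for a neuron's top vs bottom cells."""
    import matplotlib.pyplot as plt

    if isinstance(X, pd.DataFrame):
        markers, Xv = list(X.columns), X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        markers = [f"marker_{j}" for j in range(Xv.shape[1])]
    H = model.interpretable_activations(Xv)
    top, bottom = rank_split(H[:, neuron_index], fraction)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(markers), 4))
    pos = np.arange(len(markers), dtype=float)
    vt = ax.violinplot([Xv[top, j] for j in range(len(markers))],
                       positions=pos - 0.18, widths=0.32, showmedians=True)
    vb = ax.violinplot([Xv[bottom, j] for j in range(len(markers))],
                       positions=pos + 0.18, widths=0.32, showmedians=True)
    for body in vt["bodies"]:
        body.set_facecolor("tab:red")
    for body in vb["bodies"]:
        body.set_facecolor("tab:green")
    ax.set_xticks(pos, markers, rotation=90)
    ax.set_ylabel("marker value")
    ax.set_title(f"neuron {neuron_index}: top (red) vs bottom (green) "
                 f"{int(fraction * 100)}% activating cells")
    return ax


def plot_ami_profile(profile, ax=None):
    """Line plot of AMI across layers for each clusterer/reference pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for col in profile.values.columns:
        ax.plot(profile.values.index, profile.values[col], marker="o", label=col)
    ax.set_ylabel("adjusted mutual information")
    ax.set_ylim(0, 1.05)
    ax.tick_params(axis="x", rotation=45)
    ax.legend(fontsize=8)
    return ax


def plot_activation_trajectories(summary, absolute: bool = True, ax=None):
    """Per-class mean (or mean-absolute) activation across layers."""
    import matplotlib.pyplot as plt

    frame = summary.mean_abs if absolute else summary.mean
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for cls in frame.columns:
        ax.plot(frame.index, frame[cls], marker=".", label=str(cls))
    ax.set_ylabel("mean |activation|" if absolute else "mean activation")
    ax.tick_params(axis="x", rotation=45)
    ax.legend(fontsize=8, ncols=2)
    return ax
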