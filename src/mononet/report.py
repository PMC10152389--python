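"""One-shot interpretation bundle joining all analyses.

`full_report` runs, on a trained model and a labeled marker table, the KS
activation analysis, the Shapley attribution, the sign/strength matrix, the
AMI layer profile and the per-class activation summary, and assembles a
per-class narrative table: for each class, its strongest positively and
negatively coupled interpretable neurons and those neurons' top markers —
the machine-readable analogue of reading "population P is characterized by
high marker A and low marker B" off the individual figures.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import neuron_attributions
from .information_flow import activation_summary, ami_profile
from .ks import global_importance, neuron_marker_ks
from .errors import MissingLabelsError

__all__ = ["full_report", "narrative_table"]


def narrative_table(model, ks_matrix, sign_strength: pd.DataFrame,
                    top_k_markers: int = 4) -> pd.DataFrame:
    """Per-class summary of strongest neurons and their top markers.

    For each class: the neuron with the largest positive sign/strength entry
    (its activation raises the class logit the most directly), the neuron
    with the most negative entry, and each neuron's top-KS markers annotated
    with the direction the marker moves the neuron (+ high / - low).
    """
    rows = []
    for cls in sign_strength.columns:
        col = sign_strength[cls]
        pos_neuron = col.idxmax()
        neg_neuron = col.idxmin()
        entry = {"class": cls,
                 "top_positive_neuron": pos_neuron,
                 "positive_strength": float(col.max()),
                 "top_negative_neuron": neg_neuron,
                 "negative_strength": float(col.min())}
        for tag, neuron in (("positive", pos_neuron), ("negative", neg_neuron)):
            markers = ks_matrix.top_markers(neuron, k=top_k_markers)
            signed = [
                f"{m}{'+' if ks_matrix.directions.loc[neuron, m] >= 0 else '-'}"
                for m in markers
            ]
            entry[f"{tag}_neuron_markers"] = ";".join(signed)
        rows.append(entry)
    return pd.DataFrame(rows).set_index("class")


def full_report(model, X, y, fraction: float = 0.2, attribution_method: str | None = None,
                n_explained: int = 500, seed: int | None = 0,
                out_dir=None) -> dict:
    """Run the complete interpretation workflow; optionally write artifacts.

    Returns a dict with keys ``ks``, ``attribution``, ``sign_strength``,
    ``ami``, ``activations``, ``narrative``, ``global_importance``.  When
    ``out_dir`` is given, each piece is written as CSV/JSON with fixed
    formatting so regeneration under the same seed is byte-identical.
    """
    if y is None:
        raise MissingLabelsError("full_report requires a labeled table")
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if attribution_method is None:
        attribution_method = "exact" if Xdf.shape[1] <= 15 else "kernel"
    ksm = neuron_marker_ks(model, Xdf, fraction=fraction)
    attr = neuron_attributions(model, Xdf, method=attribution_method,
                               n_explained=n_explained, seed=seed)
    ss = model.sign_strength_matrix()
    # align sign/strength neuron labels with the KS matrix labels
    ss.index = ksm.neurons[: len(ss.index)] if len(ss.index) == len(ksm.neurons) else ss.index
    ami = ami_profile(model, Xdf.to_numpy(), np.asarray(y), seed=seed)
    acts = activation_summary(model, Xdf.to_numpy(), np.asarray(y))
    narrative = narrative_table(model, ksm, ss)
    gi = pd.DataFrame({
        "ks": global_importance(ksm),
        "shapley_abs": global_importance(attr),
    })
    out = {"ks": ksm, "attribution": attr, "sign_strength": ss, "ami": ami,
           "activations": acts, "narrative": narrative, "global_importance": gi}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        ksm.scores.to_csv(out_dir / "ks_scores.csv", float_format=fmt)
        ksm.directions.to_csv(out_dir / "ks_directions.csv", float_format=fmt)
        attr.values_frame.to_csv(out_dir / "shapley.csv", float_format=fmt)
        ss.to_csv(out_dir / "sign_strength.csv", float_format=fmt)
        ami.values.to_csv(out_dir / "ami_profile.csv", float_format=fmt)
        acts.mean.to_csv(out_dir / "activation_mean.csv", float_format=fmt)
        acts.mean_abs.to_csv(out_dir / "activation_mean_abs.csv", float_format=fmt)
        narrative.to_csv(out_dir / "narrative.csv")
        gi.to_csv(out_dir / "global_importance.csv", float_format=fmt)
        with open(out_dir / "report_meta.json", "w") as f:
            json.dump({"fraction": fraction, "attribution_method": attribution_method,
                       "n_explained": n_explained, "seed": seed,
                       "constant_neurons": ksm.constant_neurons,
                       "zero_variance_layers": ami.zero_variance_layers}, f, indent=2)
    return out
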