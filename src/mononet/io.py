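"""Reading marker tables and checkpointing models.

A *marker table* is a cells x markers delimited text file with a header row
and, optionally, a label column naming each cell's class.  A *checkpoint* is
a directory holding a JSON manifest (architecture, class names, marker
names, seeds, checksum) next to a single ``params.npz`` array container;
loading reproduces the saved model's outputs bit-exactly.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import LabelEncoder

from . import __version__
from .cnn import MonoCNNClassifier
from .errors import CheckpointError, InvalidParameterError
from .model import MonoNetClassifier

__all__ = ["MarkerTable", "read_marker_table", "write_marker_table",
           "save_model", "load_model"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class MarkerTable:
    """Cells x markers expression matrix with optional class labels."""

    X: pd.DataFrame
    labels: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    @property
    def markers(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_cells(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> list:
        if self.labels is None:
            return []
        return sorted(pd.unique(self.labels))


def read_marker_table(
    path,
    label_column: str | None = None,
    delimiter: str = ",",
    on_bad_rows: str = "drop",
) -> MarkerTable:
    """Load a delimited marker table; non-numeric marker cells are bad rows.

    ``on_bad_rows``: ``"drop"`` removes offending rows (the count is kept in
    ``meta["n_dropped"]``), ``"error"`` raises with the first bad location.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    if df.columns.duplicated().any():
        raise InvalidParameterError("marker names must be unique")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise InvalidParameterError(
                f"label column {label_column!r} not in file (columns: {list(df.columns)})"
            )
        labels = df[label_column].astype(str)
        df = df.drop(columns=[label_column])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad and on_bad_rows == "error":
        r = int(bad.idxmax())
        c = numeric.loc[r].isna().idxmax()
        raise InvalidParameterError(f"non-numeric marker value at row {r}, column {c!r}")
    if n_bad:
        numeric = numeric[~bad].reset_index(drop=True)
        if labels is not None:
            labels = labels[~bad].reset_index(drop=True)
    return MarkerTable(
        X=numeric,
        labels=labels,
        meta={"source": str(path), "n_dropped": n_bad, "label_column": label_column},
    )


def write_marker_table(table: MarkerTable, path, delimiter: str = ",") -> None:
    df = table.X.copy()
    if table.labels is not None:
        df[table.meta.get("label_column") or "label"] = table.labels.to_numpy()
    df.to_csv(path, sep=delimiter, index=False)


# --------------------------------------------------------------- checkpoints
def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _collect_arrays(model) -> dict[str, np.ndarray]:
    arrays = {f"head__{k}": v for k, v in model.head_.params.items()}
    if isinstance(model, MonoNetClassifier):
        arrays.update({f"block__{k}": v for k, v in model.block_.params.items()})
    else:
        arrays["conv__kernel"] = model.kernel_
        arrays["conv__bias"] = model.conv_bias_
    return arrays


def save_model(model, run_dir, marker_names: list[str] | None = None,
               extra_meta: dict | None = None) -> Path:
    """Write manifest.json + params.npz into ``run_dir`` and return its path."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    arrays = _collect_arrays(model)
    npz_path = run_dir / "params.npz"
    np.savez(npz_path, **arrays)
    manifest = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "package_version": __version__,
        "model_type": "cnn" if isinstance(model, MonoCNNClassifier) else "tabular",
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "classes": [str(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
        "marker_names": marker_names,
        "params_sha256": _sha256(npz_path),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra_meta:
        manifest.update(extra_meta)
    with open(run_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return run_dir


def load_model(run_dir):
    """Rebuild a model from a checkpoint directory, verifying the checksum.

    Returns ``(model, manifest)``.  The restored model reproduces the saved
    model's forward pass bit-exactly because the parameter container stores
    full-precision float64 arrays.
    """
    run_dir = Path(run_dir)
    try:
        with open(run_dir / "manifest.json") as f:
            manifest = json.load(f)
    except FileNotFoundError as e:
        raise CheckpointError(f"no manifest.json in {run_dir}") from e
    if manifest.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointError(
            f"checkpoint format {manifest.get('format_version')} is not "
            f"supported by this package (expects {CHECKPOINT_FORMAT_VERSION})"
        )
    npz_path = run_dir / "params.npz"
    digest = _sha256(npz_path)
    if digest != manifest["params_sha256"]:
        raise CheckpointError(
            f"params.npz checksum mismatch ({digest[:12]}... != "
            f"{manifest['params_sha256'][:12]}...); checkpoint corrupted"
        )
    arrays = dict(np.load(npz_path))
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in manifest["params"].items()}
    classes = np.asarray(manifest["classes"])
    if manifest["model_type"] == "tabular":
        model = MonoNetClassifier(**params)
        rng = np.random.default_rng(0)
        model._initialize(manifest["n_features_in"], len(classes), rng)
        for k, v in arrays.items():
            scope, name = k.split("__", 1)
            target = model.block_.params if scope == "block" else model.head_.params
            target[name][...] = v
    else:
        model = MonoCNNClassifier(**params)
        rng = np.random.default_rng(0)
        H, W = model.image_shape
        ks = model.kernel_size
        model.kernel_ = arrays["conv__kernel"]
        model.conv_bias_ = arrays["conv__bias"]
        from ._net import MonotonicHead

        model.head_ = MonotonicHead(
            model.n_interpretable_, tuple(model.monotonic_sizes), len(classes),
            transform=model.transform, activation=model.activation,
            residual=True, rng=rng,
        )
        for k, v in arrays.items():
            if k.startswith("head__"):
                model.head_.params[k.split("__", 1)[1]][...] = v
    model.classes_ = classes
    model._le_ = LabelEncoder().fit(classes)
    model.n_features_in_ = manifest["n_features_in"]
    return model, manifest
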