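"""Saving and loading trained network parameters (npz archive + JSON sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .networks import NetworkParameters

__all__ = ["save_network", "load_network"]


def save_network(
    stem: str | Path,
    params: NetworkParameters,
    meta: dict | None = None,
    loss_curve: np.ndarray | None = None,
) -> Path:
    """Write ``<stem>.npz`` (arrays) and ``<stem>.json`` (metadata sidecar)."""
    stem = Path(stem)
    arrays = dict(params.values)
    if loss_curve is not None:
        arrays["_loss_curve"] = np.asarray(loss_curve)
    np.savez_compressed(stem.with_suffix(".npz"), **arrays)
    sidecar = {"arch": params.arch, "n_units": params.n_units, **(meta or {})}
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return stem.with_suffix(".npz")


def load_network(path: str | Path) -> tuple[NetworkParameters, dict]:
    """Load a parameter archive saved by :func:`save_network`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as data:
        values = {k: data[k] for k in data.files if not k.startswith("_")}
    params = NetworkParameters(sidecar["arch"], int(sidecar["n_units"]), values)
    return params, sidecar
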