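"""Packaged optimizer / initialisation hyperparameters per environment, architecture and size.

The values were selected by a prior hyperparameter search (per environment,
architecture, and number of units) and are shipped as a data file; this
module only looks them up.  For network sizes not present in the table a
nearest-neighbour fallback in logarithmic N space is available (used by
the complexity sweep).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["HyperparameterRecord", "hyperparameter_table", "load_hyperparameters"]

_TABLE: pd.DataFrame | None = None

HEURISTIC_SGD_LEARNING_RATE = 3e-3  # selected by random search, all heuristic types


@dataclass(frozen=True)
class HyperparameterRecord:
    environment: str  # "unigram" or "bigram"
    arch: str
    n_units: int
    eta0: float
    sigma0_x: float
    sigma0_h: float
    mu0_diag: float


def hyperparameter_table() -> pd.DataFrame:
    global _TABLE
    if _TABLE is None:
        with resources.files("seqpred.data").joinpath("hyperparameters.csv").open() as f:
            _TABLE = pd.read_csv(f)
    return _TABLE


def _environment_key(environment: str) -> str:
    """Both bigram variants share the 'bigram' hyperparameter rows."""
    if environment in ("bigram", "bigram_independent", "bigram_coupled"):
        return "bigram"
    if environment == "unigram":
        return "unigram"
    raise KeyError(f"unknown environment {environment!r}")


def load_hyperparameters(
    environment: str, arch: str, n_units: int, nearest: bool = False
) -> HyperparameterRecord:
    """Look up the hyperparameter row for (environment, arch, n_units).

    With ``nearest=True``, a missing size resolves to the tabulated size
    nearest in log space (ties break toward the smaller size).
    """
    env = _environment_key(environment)
    table = hyperparameter_table()
    sub = table[(table.environment == env) & (table.arch == arch)]
    if sub.empty:
        raise KeyError(f"no hyperparameters for ({env}, {arch})")
    row = sub[sub.n_units == n_units]
    if row.empty:
        if not nearest:
            raise KeyError(f"no hyperparameters for ({env}, {arch}, N={n_units})")
        sizes = np.sort(sub.n_units.to_numpy())
        dist = np.abs(np.log(sizes) - np.log(n_units))
        row = sub[sub.n_units == sizes[int(np.argmin(dist))]]
    r = row.iloc[0]
    return HyperparameterRecord(
        environment=env,
        arch=arch,
        n_units=n_units,
        eta0=float(r.eta0),
        sigma0_x=float(r.sigma0_x),
        sigma0_h=float(r.sigma0_h),
        mu0_diag=float(r.mu0_diag),
    )
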