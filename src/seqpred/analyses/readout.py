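"""Linear readouts of latent quantities from recurrent activity.

A readout is an ordinary-least-squares map (weights + intercept) from the
N recurrent activations at one time step to a target quantity computed at
the same time step by the Bayes-optimal observer — e.g. the log precision
psi_t = -log SD of the posterior over the unigram probability, or, in the
bigram environment, the log odds of the posterior mean and the log
precision of each transition probability.  Fitting pools samples over
time steps and sequences of a training set; accuracy is the Pearson
correlation between read and target series on held-out sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ReadoutModel", "fit_readout", "evaluate_readout"]


@dataclass
class ReadoutModel:
    weights: np.ndarray
    intercept: float
    target_label: str = ""
    train_r: float = np.nan
    test_r: float = np.nan
    rank_deficient: bool = False

    def predict(self, hidden_states: np.ndarray) -> np.ndarray:
        """Apply the readout; accepts (..., N) activations."""
        return np.asarray(hidden_states) @ self.weights + self.intercept


def _pool(hidden_states: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = np.asarray(hidden_states, dtype=float)
    y = np.asarray(targets, dtype=float)
    h = h.reshape(-1, h.shape[-1])
    return h, y.reshape(-1)


def fit_readout(
    hidden_states: np.ndarray, targets: np.ndarray, target_label: str = ""
) -> ReadoutModel:
    """OLS fit with intercept; samples are pooled over leading axes.

    ``hidden_states`` has shape (..., N) and ``targets`` the matching
    leading shape.  A rank-deficient design is flagged and solved by the
    pseudo-inverse (which lstsq provides).
    """
    X, y = _pool(hidden_states, targets)
    design = np.column_stack([X, np.ones(len(X))])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    model = ReadoutModel(
        weights=coef[:-1],
        intercept=float(coef[-1]),
        target_label=target_label,
        rank_deficient=rank < design.shape[1],
    )
    model.train_r = evaluate_readout(model, hidden_states, targets)
    return model


def evaluate_readout(model: ReadoutModel, hidden_states: np.ndarray, targets: np.ndarray) -> float:
    """Pearson correlation between the read and target series."""
    X, y = _pool(hidden_states, targets)
    read = X @ model.weights + model.intercept
    if np.std(read) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    return float(stats.pearsonr(read, y).statistic)
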