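"""Projection of recurrent activity onto the prediction-precision subspace.

The prediction vector is the network's output weight vector w_hp; the
precision vector is the weight vector of the fitted precision readout.
For visualisation and analysis the precision vector is orthogonalised
against the prediction vector by one Gram-Schmidt step, and states are
expressed by their coordinates along the (normalised) prediction axis and
the orthogonalised precision axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["project_subspace", "orthogonalized_precision_axis"]

_COLLINEAR_TOL = 1e-10


def orthogonalized_precision_axis(w_pred: np.ndarray, w_prec: np.ndarray) -> np.ndarray:
    """Gram-Schmidt: remove from w_prec its component along w_pred."""
    w_pred = np.asarray(w_pred, dtype=float)
    w_prec = np.asarray(w_prec, dtype=float)
    npred = np.linalg.norm(w_pred)
    if npred == 0 or np.linalg.norm(w_prec) == 0:
        raise ValueError("axis vectors must be nonzero")
    u = w_pred / npred
    residual = w_prec - (w_prec @ u) * u
    if np.linalg.norm(residual) < _COLLINEAR_TOL * np.linalg.norm(w_prec):
        raise ValueError("degenerate subspace: precision and prediction vectors are collinear")
    return residual


def project_subspace(
    hidden_states: np.ndarray, w_pred: np.ndarray, w_prec: np.ndarray
) -> np.ndarray:
    """2-D coordinates of states: (projection on w_pred, on orthogonalised w_prec).

    ``hidden_states`` has shape (..., N); the result has shape (..., 2).
    Projections are onto unit axes.
    """
    w_pred = np.asarray(w_pred, dtype=float)
    u = w_pred / np.linalg.norm(w_pred)
    residual = orthogonalized_precision_axis(w_pred, w_prec)
    v = residual / np.linalg.norm(residual)
    h = np.asarray(hidden_states, dtype=float)
    return np.stack([h @ u, h @ v], axis=-1)
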