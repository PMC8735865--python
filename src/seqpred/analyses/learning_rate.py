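"""Moment-by-moment effective learning rate of any prediction series.

The effective learning rate normalises the update of the prediction by the
prediction error:

    alpha_{t+1} = (p_{t+1} - p_t) / (x_{t+1} - p_t),
    alpha_0     = (p_0 - 0.5) / (x_0 - 0.5)

(0.5 is the pre-sequence reference prediction shared by all agents).  For
a delta-rule agent this recovers its constant learning rate exactly; for
adaptive agents it fluctuates, peaking after suspected change points.
Steps where |x - p| < 1e-6 are masked as degenerate and excluded from
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LearningRateTrace", "effective_learning_rate"]

DEGENERATE_TOL = 1e-6


@dataclass
class LearningRateTrace:
    alpha: np.ndarray  # same leading shape as predictions; nan where invalid
    valid: np.ndarray  # boolean mask

    def masked_mean(self, axis=None):
        return np.nanmean(np.where(self.valid, self.alpha, np.nan), axis=axis)


def effective_learning_rate(
    predictions: np.ndarray, observations: np.ndarray, prior_prediction: float = 0.5
) -> LearningRateTrace:
    """Per-step effective learning rate of aligned prediction/observation series.

    Both inputs may carry a leading batch axis; output has the same shape
    as ``predictions`` (entry t is alpha_t).
    """
    p = np.asarray(predictions, dtype=float)
    x = np.asarray(observations, dtype=float)
    if p.shape != x.shape:
        raise ValueError("predictions and observations must be aligned")
    prev = np.concatenate(
        [np.full(p.shape[:-1] + (1,), prior_prediction), p[..., :-1]], axis=-1
    )
    denom = x - prev
    valid = np.abs(denom) >= DEGENERATE_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(valid, (p - prev) / np.where(valid, denom, 1.0), np.nan)
    return LearningRateTrace(alpha=alpha, valid=valid)
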