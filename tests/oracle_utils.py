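"""Independent oracles used by the test suite.

These deliberately avoid the package's filtering code paths: predictions
are computed by exact enumeration over change-point configurations, with
the latent values marginalised over the same discrete grid the observer
uses, so that for short sequences the forward filter can be checked
against a brute-force sum.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _bin_values(n_bins: int) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) / n_bins


def _segment_likelihood(governed: np.ndarray, successes: np.ndarray, config, n_bins: int) -> float:
    """Likelihood of one latent's observations given its redraw configuration.

    ``config`` has one entry per time step from 1 on (1 = redraw before
    that step).  ``governed`` marks the steps this latent generated;
    ``successes`` the steps whose outcome equals the latent's "success".
    The latent is uniform over the grid independently per segment.
    """
    v = _bin_values(n_bins)
    T = governed.size
    boundaries = np.flatnonzero(np.concatenate(([1], np.asarray(config, dtype=int))))
    boundaries = np.append(boundaries, T)
    lik = 1.0
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        idx = np.arange(lo, hi)
        idx = idx[governed[idx]]
        if idx.size == 0:
            continue
        a = successes[idx].sum()
        b = idx.size - a
        lik *= float(np.mean(v**a * (1.0 - v) ** b))
    return lik


def _config_prob(config, pc: float) -> float:
    c = np.asarray(config, dtype=float)
    return float(np.prod(np.where(c == 1, pc, 1.0 - pc)))


def enumeration_sequence_prob(x: np.ndarray, structure: str, pc: float, n_bins: int = 20) -> float:
    """P(x_0..x_{T-1}) by summing over all change-point configurations."""
    x = np.asarray(x, dtype=int)
    T = x.size
    if structure == "unigram":
        governed = np.ones(T, dtype=bool)
        successes = x.astype(bool)
        total = 0.0
        for config in product((0, 1), repeat=T - 1):
            total += _config_prob(config, pc) * _segment_likelihood(
                governed, successes, config, n_bins
            )
        return total

    prev = np.concatenate(([0], x[:-1]))
    gov00 = prev == 0
    gov11 = prev == 1
    succ00 = (1 - x).astype(bool)  # p00's success is repeating the 0
    succ11 = x.astype(bool)
    total = 0.0
    if structure == "bigram_coupled":
        for config in product((0, 1), repeat=T - 1):
            lik = _segment_likelihood(gov00, succ00, config, n_bins) * _segment_likelihood(
                gov11, succ11, config, n_bins
            )
            total += _config_prob(config, pc) * lik
    else:
        for c00 in product((0, 1), repeat=T - 1):
            l00 = _segment_likelihood(gov00, succ00, c00, n_bins)
            p00 = _config_prob(c00, pc)
            for c11 in product((0, 1), repeat=T - 1):
                total += (
                    p00
                    * _config_prob(c11, pc)
                    * l00
                    * _segment_likelihood(gov11, succ11, c11, n_bins)
                )
    return total


def enumeration_predictions(x: np.ndarray, structure: str, pc: float, n_bins: int = 20) -> np.ndarray:
    """p_t = P(x_{t+1} = 1 | x_0..x_t) by exact enumeration, for every t."""
    x = np.asarray(x, dtype=int)
    preds = np.empty(x.size)
    for t in range(x.size):
        prefix = x[: t + 1]
        den = enumeration_sequence_prob(prefix, structure, pc, n_bins)
        num = enumeration_sequence_prob(np.append(prefix, 1), structure, pc, n_bins)
        preds[t] = num / den
    return preds
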