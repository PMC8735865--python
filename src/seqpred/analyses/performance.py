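"""Prediction performance expressed as the % of optimal log likelihood.

An agent's sequence log likelihood L (sum over scored steps of
log[x_{t+1} p_t + (1 - x_{t+1})(1 - p_t)]) is rescaled affinely so that a
constant prediction of 0.5 scores 0 % and the Bayes-optimal observer for
the generating environment scores 100 %:

    percent = (L - L_chance) / (L_optimal - L_chance) * 100
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PerformanceReport",
    "percent_optimal",
    "chance_log_likelihood",
    "trace_log_likelihood",
    "group_performance",
]


def trace_log_likelihood(predictions: np.ndarray, observations: np.ndarray) -> float | np.ndarray:
    """Log likelihood of a prediction series against its sequence (p_t vs x_{t+1})."""
    p = np.asarray(predictions)[..., :-1]
    x = np.asarray(observations)[..., 1:]
    return np.log(x * p + (1 - x) * (1 - p)).sum(axis=-1)


def chance_log_likelihood(observations: np.ndarray) -> float:
    """Log likelihood of the constant-0.5 agent (scored steps only)."""
    obs = np.atleast_2d(np.asarray(observations))
    return -float(obs[:, 1:].size) * np.log(2.0)


def percent_optimal(L: float, L_optimal: float, L_chance: float) -> float:
    if L_optimal <= L_chance:
        raise ValueError("invalid reference: L_optimal must exceed L_chance")
    return (L - L_chance) / (L_optimal - L_chance) * 100.0


@dataclass
class PerformanceReport:
    """Per-agent % of optimal log likelihood with a group mean and 95 % CI."""

    percents: np.ndarray
    mean: float
    ci95: tuple[float, float]
    L_optimal: float
    L_chance: float


def group_performance(agent_lls: np.ndarray, L_optimal: float, L_chance: float) -> PerformanceReport:
    """Summarise a group of agents' total log likelihoods on a shared test set.

    The 95 % CI of the group mean uses the Student t interval on the
    replicate values.
    """
    percents = np.asarray(
        [percent_optimal(ll, L_optimal, L_chance) for ll in np.atleast_1d(agent_lls)]
    )
    mean = float(percents.mean())
    if percents.size > 1:
        half = stats.t.ppf(0.975, percents.size - 1) * stats.sem(percents)
    else:
        half = np.nan
    return PerformanceReport(
        percents=percents,
        mean=mean,
        ci95=(mean - half, mean + half),
        L_optimal=L_optimal,
        L_chance=L_chance,
    )
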