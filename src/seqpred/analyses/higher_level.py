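"""Test of higher-level inference: transferring change suspicion between bigrams.

Agents trained (or configured) with *coupled* change points should treat a
surprising streak of repetitions of one bigram as evidence that *both*
bigram probabilities may have changed; agents assuming *independent*
change points should not.  The probe measures the prediction about the
unobserved bigram just before and just after a streak of m repetitions of
the observed bigram's value:

1. run the agent on a 74-observation prefix (observed bigram probability
   0.2, unobserved 0.2 or 0.8, no change points);
2. query p_before by feeding the query input ('0' if the unobserved
   bigram is 0|0, else '1') and reading the prediction;
3. feed m repetitions of the observed value;
4. query again and read p_after.

The statistic is |p_after - p_before| averaged over the 400 probes, per
streak length m in [2, 75].  Queries advance the agent's state, as they
do for a human observer receiving those observations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..environments import EnvironmentConfig, ProbeSet
from ..networks import NetworkParameters, network_output, network_step
from ..optimal import LatentGrid, bayes_update, summarize, transition, uniform_state

__all__ = [
    "network_streak_curve",
    "optimal_streak_curve",
    "streak_transfer_curve",
    "streak_transfer_experiment",
]

DEFAULT_STREAK_LENGTHS = tuple(range(2, 76))


def _curve_from_stepper(init_state, step, output, probes: ProbeSet, streak_lengths):
    """Shared driver: run prefix+query once, then extend per streak length.

    ``step(state, x_batch) -> state`` consumes one observation per probe;
    ``output(state) -> p_batch`` reads the current prediction.
    """
    lengths = np.asarray(sorted(streak_lengths), dtype=int)
    B = probes.n_probes
    state = init_state(B)
    for t in range(probes.prefix_length):
        state = step(state, probes.prefixes[:, t].astype(float))
    query = probes.query_value.astype(float)
    streak_value = probes.observed_value.astype(float)
    state = step(state, query)
    p_before = output(state)

    curve = np.empty(lengths.size)
    m_done = 0
    for i, m in enumerate(lengths):
        for _ in range(m - m_done):
            state = step(state, streak_value)
        m_done = int(m)
        # query on a copy so the main state keeps only streak observations
        p_after = output(step(state, query))
        curve[i] = np.abs(p_after - p_before).mean()
    return lengths, curve


def network_streak_curve(
    params: NetworkParameters, probes: ProbeSet, streak_lengths=DEFAULT_STREAK_LENGTHS
):
    """|p_after - p_before| curve of one trained network."""
    return _curve_from_stepper(
        lambda B: np.zeros((B, params.n_units)),
        lambda h, x: network_step(params, h, x),
        lambda h: network_output(params, h),
        probes,
        streak_lengths,
    )


def optimal_streak_curve(
    config: EnvironmentConfig,
    probes: ProbeSet,
    streak_lengths=DEFAULT_STREAK_LENGTHS,
    n_bins: int = 20,
):
    """Reference curve of the Bayes-optimal observer under ``config``'s assumption.

    ``config.structure`` selects the assumed coupling of change points
    (``bigram_coupled`` vs ``bigram_independent``).
    """
    grid = LatentGrid(n_bins)

    def init(B):
        return uniform_state(config.structure, n_bins, batch_shape=(B,))

    def step(state, x):
        state = bayes_update(state, x.astype(int), grid)
        return transition(state, config.change_prob)

    def output(state):
        p, _, _, _ = summarize(state, grid)
        return p

    return _curve_from_stepper(init, step, output, probes, streak_lengths)


def streak_transfer_curve(trace_fn, probes: ProbeSet, streak_lengths=DEFAULT_STREAK_LENGTHS):
    """Curve for an arbitrary agent given ``trace_fn(obs_batch) -> predictions``.

    Used for baseline agents without an exposed incremental state (e.g.
    heuristics): the full input (prefix + query + streak + query) is
    re-run per streak length.
    """
    lengths = np.asarray(sorted(streak_lengths), dtype=int)
    query = probes.query_value[:, None]
    streak_value = probes.observed_value[:, None]
    base = np.concatenate([probes.prefixes, query], axis=1)
    p_before = trace_fn(base)[:, -1]
    curve = np.empty(lengths.size)
    for i, m in enumerate(lengths):
        full = np.concatenate([base, np.repeat(streak_value, m, axis=1), query], axis=1)
        p_after = trace_fn(full)[:, -1]
        curve[i] = np.abs(p_after - p_before).mean()
    return lengths, curve


def streak_transfer_experiment(curves_coupled: np.ndarray, curves_independent: np.ndarray) -> dict:
    """Group comparison of coupled-trained vs independent-trained curves.

    Inputs are (n_agents, n_streak_lengths) arrays of |p_after - p_before|
    means.  Returns per-length group means and a one-tailed two-sample
    t-test (coupled > independent) on the per-agent means over lengths.
    """
    cc = np.atleast_2d(curves_coupled)
    ci = np.atleast_2d(curves_independent)
    res = stats.ttest_ind(cc.mean(axis=1), ci.mean(axis=1), alternative="greater")
    return {
        "mean_coupled": cc.mean(axis=0),
        "mean_independent": ci.mean(axis=0),
        "t": float(res.statistic),
        "p": float(res.pvalue),
    }
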