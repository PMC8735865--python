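"""Exact Bayesian observer via forward filtering on a discretised latent grid.

The generative processes in :mod:`seqpred.environments` are hidden Markov
models once the latent probabilities are discretised.  Each latent
probability is binned into ``n_bins`` equal-width bins (default 20, bin
centers (k + 0.5)/n_bins); the observer maintains a posterior mass over
the grid (20 cells for the unigram environment, a 20 x 20 joint for the
bigram environments) and alternates

* a Bayes update with the incoming observation (Bernoulli likelihood per
  cell, conditioned on the previous observation in the bigram case), and
* a transition step applying the change-point hazard: with probability
  ``p_c`` each latent is redrawn uniformly (jointly for coupled change
  points, independently otherwise).

The emitted prediction p_t is the expected probability that the next
observation equals 1 under the *transitioned* (predictive) posterior, and
the per-latent summary statistics (posterior mean, SD sigma_t, and log
precision psi_t = -log sigma_t) are computed on that same predictive
posterior.  Filtering is done in linear space with per-step
renormalisation; with at most 400 cells and bin values strictly inside
(0, 1) there is no underflow risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environments import EnvironmentConfig, GeneratedSequence

__all__ = [
    "LatentGrid",
    "PosteriorState",
    "PosteriorTrace",
    "transition",
    "bayes_update",
    "summarize",
    "run_optimal_agent",
    "run_optimal_batch",
]

DEFAULT_N_BINS = 20


@dataclass(frozen=True)
class LatentGrid:
    """Equal-width discretisation of [0, 1] with bin-center representatives."""

    n_bins: int = DEFAULT_N_BINS

    @property
    def values(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


@dataclass
class PosteriorState:
    """Posterior mass over the latent grid plus the last consumed observation.

    ``mass`` has shape (..., n_bins) for the unigram structure and
    (..., n_bins, n_bins) for bigram structures, where leading axes index a
    batch of sequences filtered in parallel.  Axis order for bigram mass is
    (p00, p11).
    """

    mass: np.ndarray
    structure: str
    prev_obs: np.ndarray | int = 0

    def check_normalized(self, tol: float = 1e-12) -> None:
        axes = (-1,) if self.structure == "unigram" else (-2, -1)
        total = self.mass.sum(axis=axes)
        if not np.allclose(total, 1.0, atol=tol):
            raise ValueError("posterior mass is not normalised")


@dataclass
class PosteriorTrace:
    """Per-step output of the optimal observer on one sequence (or a batch).

    ``predictions[t]`` is P(x_{t+1} = 1 | x_0..x_t).  ``means``, ``sds``
    and ``log_precisions`` have one row per latent variable and are
    computed on the predictive posterior, i.e. mean/SD of the latent at
    t + 1 given x_0..x_t; ``log_precisions = -log(sds)``.
    ``log_likelihood`` is the sum over t = 0..T-2 of
    log[x_{t+1} p_t + (1 - x_{t+1})(1 - p_t)].
    """

    predictions: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_precisions: np.ndarray
    log_likelihood: float | np.ndarray
    latent_names: tuple[str, ...]


def uniform_state(structure: str, n_bins: int = DEFAULT_N_BINS, batch_shape: tuple = ()) -> PosteriorState:
    """Uniform prior over the grid (the observer's state before any data)."""
    if structure == "unigram":
        shape = batch_shape + (n_bins,)
    else:
        shape = batch_shape + (n_bins, n_bins)
    mass = np.full(shape, 1.0 / (n_bins if structure == "unigram" else n_bins**2))
    prev = np.zeros(batch_shape, dtype=np.int8) if batch_shape else 0
    return PosteriorState(mass, structure, prev)


def transition(state: PosteriorState, change_prob: float) -> PosteriorState:
    """Apply the change-point hazard to the posterior mass.

    unigram / bigram_coupled: mass' = (1 - p_c) mass + p_c * uniform.
    bigram_independent: the redraw kernel factorises across the two latent
    axes; it is applied along each axis separately.
    """
    m = state.mass
    pc = change_prob
    if state.structure == "unigram":
        n = m.shape[-1]
        out = (1.0 - pc) * m + pc * m.sum(axis=-1, keepdims=True) / n
    elif state.structure == "bigram_coupled":
        n2 = m.shape[-1] * m.shape[-2]
        out = (1.0 - pc) * m + pc * m.sum(axis=(-2, -1), keepdims=True) / n2
    else:  # bigram_independent
        n = m.shape[-1]
        out = (1.0 - pc) * m + pc * m.sum(axis=-2, keepdims=True) / n
        out = (1.0 - pc) * out + pc * out.sum(axis=-1, keepdims=True) / n
    return PosteriorState(out, state.structure, state.prev_obs)


def _likelihood(structure: str, grid: LatentGrid, obs, prev_obs) -> np.ndarray:
    v = grid.values
    if structure == "unigram":
        obs_a = np.asarray(obs, dtype=float)
        return obs_a[..., None] * v + (1.0 - obs_a[..., None]) * (1.0 - v)
    # bigram: likelihood depends on which transition was observed
    obs_a = np.asarray(obs, dtype=float)[..., None, None]
    prev_a = np.asarray(prev_obs, dtype=float)[..., None, None]
    p00 = v[:, None]  # axis -2
    p11 = v[None, :]  # axis -1
    lik_prev1 = obs_a * p11 + (1.0 - obs_a) * (1.0 - p11)
    lik_prev0 = (1.0 - obs_a) * p00 + obs_a * (1.0 - p00)
    return prev_a * lik_prev1 + (1.0 - prev_a) * lik_prev0


def bayes_update(state: PosteriorState, obs, grid: LatentGrid | None = None) -> PosteriorState:
    """Multiply the mass by the Bernoulli likelihood of ``obs`` and renormalise."""
    if grid is None:
        grid = LatentGrid(state.mass.shape[-1])
    lik = _likelihood(state.structure, grid, obs, state.prev_obs)
    m = state.mass * lik
    axes = (-1,) if state.structure == "unigram" else (-2, -1)
    total = m.sum(axis=axes, keepdims=True)
    if np.any(total <= 0):
        raise FloatingPointError("posterior mass underflow in Bayes update")
    m = m / total
    prev = np.asarray(obs, dtype=np.int8) if np.ndim(obs) else int(obs)
    return PosteriorState(m, state.structure, prev)


def _marginal_stats(mass: np.ndarray, values: np.ndarray, axis_keep: int, joint: bool):
    """Mean and SD of one marginal of the (batched, possibly joint) mass."""
    if joint:
        other = -1 if axis_keep == -2 else -2
        marg = mass.sum(axis=other)
    else:
        marg = mass
    mean = (marg * values).sum(axis=-1)
    var = (marg * values**2).sum(axis=-1) - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0))


def summarize(state: PosteriorState, grid: LatentGrid | None = None):
    """Prediction and per-latent (mean, SD, psi) of a predictive posterior.

    Returns ``(prediction, means, sds, psis)`` where the latent axis is the
    leading axis of the three summary arrays (1 latent for unigram, 2 for
    bigram, ordered (p00, p11)).
    """
    if grid is None:
        grid = LatentGrid(state.mass.shape[-1])
    v = grid.values
    if state.structure == "unigram":
        mean, sd = _marginal_stats(state.mass, v, -1, joint=False)
        if np.any(sd <= 0):
            raise FloatingPointError("degenerate (point-mass) posterior: SD = 0")
        return mean, np.stack([mean]), np.stack([sd]), np.stack([-np.log(sd)])
    mean00, sd00 = _marginal_stats(state.mass, v, -2, joint=True)
    mean11, sd11 = _marginal_stats(state.mass, v, -1, joint=True)
    if np.any(sd00 <= 0) or np.any(sd11 <= 0):
        raise FloatingPointError("degenerate (point-mass) posterior: SD = 0")
    prev = np.asarray(state.prev_obs, dtype=float)
    prediction = prev * mean11 + (1.0 - prev) * (1.0 - mean00)
    means = np.stack([mean00, mean11])
    sds = np.stack([sd00, sd11])
    return prediction, means, sds, -np.log(sds)


def run_optimal_batch(
    observations: np.ndarray,
    config: EnvironmentConfig,
    n_bins: int = DEFAULT_N_BINS,
) -> PosteriorTrace:
    """Filter a batch of sequences (rows of ``observations``) in parallel.

    Per step: Bayes-update with x_t, apply the hazard, then summarise the
    predictive posterior into p_t and the per-latent statistics.
    """
    obs = np.atleast_2d(np.asarray(observations))
    B, T = obs.shape
    grid = LatentGrid(n_bins)
    L = 1 if config.structure == "unigram" else 2
    state = uniform_state(config.structure, n_bins, batch_shape=(B,))
    predictions = np.empty((B, T))
    means = np.empty((L, B, T))
    sds = np.empty((L, B, T))
    for t in range(T):
        state = bayes_update(state, obs[:, t], grid)
        state = transition(state, config.change_prob)
        p, m, s, _ = summarize(state, grid)
        predictions[:, t] = p
        means[:, :, t] = m
        sds[:, :, t] = s
    with np.errstate(divide="ignore"):
        log_precisions = -np.log(sds)
    x_next = obs[:, 1:]
    p = predictions[:, :-1]
    ll = np.log(x_next * p + (1 - x_next) * (1 - p)).sum(axis=1)
    return PosteriorTrace(
        predictions=predictions,
        means=np.moveaxis(means, 1, 0),  # (B, L, T)
        sds=np.moveaxis(sds, 1, 0),
        log_precisions=np.moveaxis(log_precisions, 1, 0),
        log_likelihood=ll,
        latent_names=config.latent_names,
    )


def run_optimal_agent(
    sequence: GeneratedSequence | np.ndarray,
    config: EnvironmentConfig,
    n_bins: int = DEFAULT_N_BINS,
) -> PosteriorTrace:
    """Run the observer on a single sequence.

    ``config`` names the environment the observer *assumes* (it may differ
    from the generating one for cross-environment tests).
    """
    obs = sequence.observations if isinstance(sequence, GeneratedSequence) else np.asarray(sequence)
    batch = run_optimal_batch(obs[None, :], config, n_bins)
    return PosteriorTrace(
        predictions=batch.predictions[0],
        means=batch.means[0],
        sds=batch.sds[0],
        log_precisions=batch.log_precisions[0],
        log_likelihood=float(batch.log_likelihood[0]),
        latent_names=batch.latent_names,
    )
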