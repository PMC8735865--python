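"""Synthetic environments generating binary sequences with changing latent probabilities.

Three generative processes are implemented.  In all of them a sequence of
binary observations ``x_t`` is drawn one step at a time from Bernoulli
distributions whose parameters are latent probabilities that occasionally
jump ("change points"):

* ``unigram`` — a single latent base rate ``p(1)``; at each step ``t >= 1``
  it is redrawn uniformly on [0, 1] with probability ``change_prob``,
  otherwise carried over.
* ``bigram_independent`` — two latent transition probabilities ``p(0|0)``
  and ``p(1|1)``; each has its own independent change points.  The
  observation at ``t`` is drawn from ``p(1|1)`` if ``x_{t-1} = 1`` and from
  ``1 - p(0|0)`` otherwise; the observation before the sequence starts is
  taken to be 0.
* ``bigram_coupled`` — same two latents, but their change points occur
  simultaneously (a single higher-level change process).

Sequence length defaults to T = 380 and the change probability to 1/75,
the regime used throughout the accompanying analyses.

Randomness is organised as one ``numpy`` Generator stream per sequence,
derived from ``(seed, sequence_index)``, so datasets are bit-reproducible
regardless of the order in which sequences are materialised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRUCTURES",
    "EnvironmentConfig",
    "GeneratedSequence",
    "ProbeSet",
    "generate_sequence",
    "generate_dataset",
    "generate_batch",
    "generate_locked_batch",
    "generate_streak_probes",
    "sequence_to_frame",
]

STRUCTURES = ("unigram", "bigram_independent", "bigram_coupled")

DEFAULT_LENGTH = 380
DEFAULT_CHANGE_PROB = 1.0 / 75.0


@dataclass(frozen=True)
class EnvironmentConfig:
    """Parameters of one generative process.

    Parameters
    ----------
    structure:
        One of ``"unigram"``, ``"bigram_independent"``, ``"bigram_coupled"``.
    change_prob:
        Per-step probability that a latent probability is redrawn
        uniformly on [0, 1] (applies from t = 1 on; the value at t = 0 is
        the initial draw and is never flagged as a change).
    length:
        Number of observations T in one sequence.
    seed:
        Base seed from which per-sequence random streams are derived.
    """

    structure: str = "unigram"
    change_prob: float = DEFAULT_CHANGE_PROB
    length: int = DEFAULT_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown structure {self.structure!r}; expected one of {STRUCTURES}"
            )
        if not 0.0 <= self.change_prob <= 1.0:
            raise ValueError("change_prob must lie in [0, 1]")
        if self.length < 1:
            raise ValueError("length must be >= 1")

    @property
    def n_latents(self) -> int:
        return 1 if self.structure == "unigram" else 2

    @property
    def latent_names(self) -> tuple[str, ...]:
        if self.structure == "unigram":
            return ("p1",)
        return ("p00", "p11")

    @property
    def is_bigram(self) -> bool:
        return self.structure != "unigram"


@dataclass
class GeneratedSequence:
    """One realisation of an environment.

    ``latents`` has shape (n_latents, T), ``change_flags`` the same shape
    (boolean; True where the corresponding latent was redrawn at that step).
    """

    observations: np.ndarray
    latents: np.ndarray
    change_flags: np.ndarray
    config: EnvironmentConfig
    latent_names: tuple[str, ...] = field(default=("p1",))

    @property
    def length(self) -> int:
        return int(self.observations.shape[0])


@dataclass
class ProbeSet:
    """Streak probes for the higher-level (change-transfer) inference test.

    Each probe is a 74-observation prefix generated from fixed bigram
    probabilities (no change points): the "observed" bigram has probability
    0.2 (so a later streak of repetitions is surprising) and the unobserved
    bigram has probability 0.2 or 0.8.  Querying and streak construction
    are done by the analysis code; this container only carries the
    prefixes and their condition labels.
    """

    prefixes: np.ndarray  # (n_probes, prefix_length) int8
    observed_bigram: np.ndarray  # (n_probes,) int8: 0 -> "0|0", 1 -> "1|1"
    unobserved_prob: np.ndarray  # (n_probes,) float
    prefix_length: int = 74

    @property
    def n_probes(self) -> int:
        return int(self.prefixes.shape[0])

    @property
    def observed_value(self) -> np.ndarray:
        """Observation value whose repetition forms the streak (0 or 1)."""
        return self.observed_bigram

    @property
    def query_value(self) -> np.ndarray:
        """Input used to query the prediction about the unobserved bigram."""
        return 1 - self.observed_bigram


def _sequence_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _draw_latents(
    config: EnvironmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw piecewise-constant latent trajectories and their change flags."""
    T = config.length
    L = config.n_latents
    flags = np.zeros((L, T), dtype=bool)
    if T > 1:
        if config.structure == "bigram_coupled":
            shared = rng.random(T - 1) < config.change_prob
            flags[:, 1:] = shared[None, :]
        else:
            flags[:, 1:] = rng.random((L, T - 1)) < config.change_prob
    latents = np.empty((L, T), dtype=float)
    for k in range(L):
        # one uniform draw at t=0 plus one per change event, held constant between
        draw_times = np.flatnonzero(np.concatenate(([True], flags[k, 1:])))
        values = rng.random(draw_times.size)
        segment = np.cumsum(np.concatenate(([True], flags[k, 1:]))) - 1
        latents[k] = values[segment]
    return latents, flags


def _sample_observations(
    config: EnvironmentConfig, latents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    T = config.length
    u = rng.random(T)
    if config.structure == "unigram":
        return (u < latents[0]).astype(np.int8)
    p00, p11 = latents
    obs = np.empty(T, dtype=np.int8)
    prev = 0
    for t in range(T):
        prob_one = p11[t] if prev == 1 else 1.0 - p00[t]
        prev = 1 if u[t] < prob_one else 0
        obs[t] = prev
    return obs


def generate_sequence(
    config: EnvironmentConfig, rng: np.random.Generator | None = None, index: int = 0
) -> GeneratedSequence:
    """Generate one sequence.

    If ``rng`` is None, the per-sequence stream derived from
    ``(config.seed, index)`` is used.
    """
    if rng is None:
        rng = _sequence_rng(config.seed, index)
    latents, flags = _draw_latents(config, rng)
    obs = _sample_observations(config, latents, rng)
    return GeneratedSequence(obs, latents, flags, config, config.latent_names)


def generate_dataset(config: EnvironmentConfig, n: int) -> list[GeneratedSequence]:
    """Generate ``n`` sequences with per-sequence streams (seed, 0..n-1)."""
    return [generate_sequence(config, index=i) for i in range(n)]


def generate_batch(config: EnvironmentConfig, n: int, start_index: int = 0) -> np.ndarray:
    """Observations of ``n`` sequences stacked as an (n, T) int8 array."""
    return np.stack(
        [generate_sequence(config, index=start_index + i).observations for i in range(n)]
    )


def generate_locked_batch(
    config: EnvironmentConfig,
    locked_times: Sequence[int],
    n: int,
) -> list[GeneratedSequence]:
    """Sequences whose change points are locked at the same time steps.

    Every latent is redrawn exactly at ``locked_times`` (strictly
    increasing, within [1, T-1]) in every sequence, and nowhere else;
    latent values and observations remain random per sequence.
    """
    locked = np.asarray(locked_times, dtype=int)
    if locked.size and (locked.min() < 1 or locked.max() >= config.length):
        raise ValueError("locked change times must lie in [1, T-1]")
    if locked.size > 1 and np.any(np.diff(locked) <= 0):
        raise ValueError("locked change times must be strictly increasing")

    T, L = config.length, config.n_latents
    flags = np.zeros((L, T), dtype=bool)
    flags[:, locked] = True
    segment = np.cumsum(np.concatenate(([True], flags[0, 1:]))) - 1
    n_segments = int(segment[-1]) + 1

    out = []
    for i in range(n):
        rng = _sequence_rng(config.seed, i)
        latents = np.empty((L, T), dtype=float)
        for k in range(L):
            values = rng.random(n_segments)
            latents[k] = values[segment]
        obs = _sample_observations(config, latents, rng)
        out.append(GeneratedSequence(obs, latents, flags.copy(), config, config.latent_names))
    return out


def generate_streak_probes(
    change_prob_context: float = DEFAULT_CHANGE_PROB,
    n_per_condition: int = 100,
    prefix_length: int = 74,
    observed_prob: float = 0.2,
    unobserved_probs: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> ProbeSet:
    """Generate the probe prefixes for the higher-level inference test.

    Conditions are the cross of (observed bigram identity in {0|0, 1|1}) x
    (unobserved bigram probability in ``unobserved_probs``), with
    ``n_per_condition`` sequences each (400 total at the default 100).
    Prefixes are generated from the stated fixed bigram probabilities with
    no change points.
    """
    prefixes = []
    observed_ids = []
    unobs_ps = []
    index = 0
    for observed_id in (0, 1):  # 0 -> observed bigram is 0|0, 1 -> 1|1
        for p_unobs in unobserved_probs:
            for _ in range(n_per_condition):
                rng = _sequence_rng(seed, index)
                index += 1
                if observed_id == 1:
                    p11, p00 = observed_prob, p_unobs
                else:
                    p00, p11 = observed_prob, p_unobs
                cfg = EnvironmentConfig(
                    "bigram_independent", change_prob=0.0, length=prefix_length, seed=seed
                )
                latents = np.stack(
                    [np.full(prefix_length, p00), np.full(prefix_length, p11)]
                )
                obs = _sample_observations(cfg, latents, rng)
                prefixes.append(obs)
                observed_ids.append(observed_id)
                unobs_ps.append(p_unobs)
    return ProbeSet(
        prefixes=np.stack(prefixes),
        observed_bigram=np.asarray(observed_ids, dtype=np.int8),
        unobserved_prob=np.asarray(unobs_ps, dtype=float),
        prefix_length=prefix_length,
    )


def sequence_to_frame(seq: GeneratedSequence) -> pd.DataFrame:
    """Columnar view of one sequence (t, x, latents, change flags)."""
    data: dict[str, np.ndarray] = {
        "t": np.arange(seq.length),
        "x": seq.observations.astype(int),
    }
    for k, name in enumerate(seq.latent_names):
        data[name] = seq.latents[k]
        data[f"change_{name}"] = seq.change_flags[k].astype(int)
    return pd.DataFrame(data)
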