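"""The four small recurrent architectures: parameters, initialisation, forward dynamics.

All architectures share a three-layer template: one binary input unit, N
recurrent units (default 11), and one sigmoid output unit emitting the
prediction p_t = P(x_{t+1} = 1).  The recurrent update of the full model
is a GRU-style gated step,

    r_{t+1} = sigmoid(w_xr x_{t+1} + b_xr + h_t W_hr + b_hr)
    z_{t+1} = sigmoid(w_xz x_{t+1} + b_xz + h_t W_hz + b_hz)
    h_{t+1} = z_{t+1} * h_t
              + (1 - z_{t+1}) * tanh(w_xh x_{t+1} + b_xh
                                     + r_{t+1} * (h_t W_hh) + b_hh)

with h_{-1} = 0.  The reset gate multiplies only the recurrent drive
inside the tanh; the bias b_hh sits outside the gated product.  The
ablations are:

* ``no_gating`` — r = 1, z = 0, i.e. a vanilla (Elman) tanh network; the
  r/z parameter sets do not exist.
* ``no_lateral`` — off-diagonal entries of all recurrent matrices are
  identically zero (each unit filters the input on its own, with gating).
* ``frozen_recurrence`` — gated dynamics, but only the output weights and
  bias are trainable (reservoir computing).

Weight matrices are stored with shape (N, N) and orientation W[j, i] =
weight from unit j to unit i, so the recurrent drive is ``h @ W``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heuristics import AgentTrace

__all__ = [
    "ARCHITECTURES",
    "NetworkParameters",
    "initialize_network",
    "network_step",
    "network_output",
    "run_network",
    "forward_batch",
]

ARCHITECTURES = ("gated", "no_gating", "no_lateral", "frozen_recurrence")

GATED_KEYS = (
    "w_xr", "b_xr", "w_xz", "b_xz", "w_xh", "b_xh",
    "W_hr", "b_hr", "W_hz", "b_hz", "W_hh", "b_hh",
    "w_hp", "b_hp",
)
NO_GATING_KEYS = ("w_xh", "b_xh", "W_hh", "b_hh", "w_hp", "b_hp")


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class NetworkParameters:
    """Weights and biases of one network, plus its architecture tag.

    ``values`` maps parameter names to arrays: per-unit input weights and
    biases (shape (N,)), recurrent matrices (N, N), output weights (N,)
    and scalar output bias ``b_hp`` (shape ()).
    """

    arch: str
    n_units: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_gates(self) -> bool:
        return self.arch != "no_gating"

    @property
    def keys(self) -> tuple[str, ...]:
        return NO_GATING_KEYS if self.arch == "no_gating" else GATED_KEYS

    @property
    def trainable_keys(self) -> tuple[str, ...]:
        if self.arch == "frozen_recurrence":
            return ("w_hp", "b_hp")
        return self.keys

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.arch, self.n_units, {k: v.copy() for k, v in self.values.items()}
        )


def initialize_network(
    arch: str,
    n_units: int,
    sigma0_x: float,
    sigma0_h: float,
    mu0_diag: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NetworkParameters:
    """Random initialisation.

    Biases ~ Uniform[-1/N, 1/N]; output weights ~ Normal(0, (1/N)^2);
    input weights ~ Normal(0, sigma0_x^2); recurrent weights ~
    Normal(0, sigma0_h^2) off-diagonal and Normal(mu0_diag, sigma0_h^2)
    on the diagonal.  ``no_lateral`` zeroes the off-diagonal entries.
    """
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}")
    rng = rng or np.random.default_rng()
    N = n_units
    b = 1.0 / N
    params = NetworkParameters(arch, N)
    gate_tags = ("h",) if arch == "no_gating" else ("r", "z", "h")
    for tag in gate_tags:
        params.values[f"w_x{tag}"] = rng.normal(0.0, sigma0_x, size=N)
        params.values[f"b_x{tag}"] = rng.uniform(-b, b, size=N)
        W = rng.normal(0.0, sigma0_h, size=(N, N))
        np.fill_diagonal(W, rng.normal(mu0_diag, sigma0_h, size=N))
        if arch == "no_lateral":
            W *= np.eye(N)
        params.values[f"W_h{tag}"] = W
        params.values[f"b_h{tag}"] = rng.uniform(-b, b, size=N)
    params.values["w_hp"] = rng.normal(0.0, 1.0 / N, size=N)
    params.values["b_hp"] = np.asarray(rng.uniform(-b, b))
    return params


def network_step(params: NetworkParameters, h: np.ndarray, x) -> np.ndarray:
    """One recurrent update; ``h`` may carry leading batch axes."""
    h_new, _ = _step_with_cache(params, np.asarray(h, dtype=float), np.asarray(x, dtype=float))
    return h_new


def _step_with_cache(params: NetworkParameters, h: np.ndarray, x: np.ndarray):
    """Shared forward step; returns (h_new, cache-for-backward)."""
    v = params.values
    if h.shape[-1] != params.n_units:
        raise ValueError("state dimension does not match n_units")
    x = x[..., None]  # broadcast scalar input over units
    if params.arch == "no_gating":
        a_c = x * v["w_xh"] + v["b_xh"] + h @ v["W_hh"] + v["b_hh"]
        c = np.tanh(a_c)
        return c, (h, x, None, None, None, c)
    r = _sigmoid(x * v["w_xr"] + v["b_xr"] + h @ v["W_hr"] + v["b_hr"])
    z = _sigmoid(x * v["w_xz"] + v["b_xz"] + h @ v["W_hz"] + v["b_hz"])
    s = h @ v["W_hh"]
    c = np.tanh(x * v["w_xh"] + v["b_xh"] + r * s + v["b_hh"])
    h_new = z * h + (1.0 - z) * c
    return h_new, (h, x, r, z, s, c)


def network_output(params: NetworkParameters, h: np.ndarray) -> np.ndarray:
    """Sigmoid readout p = sigma(h . w_hp + b_hp)."""
    logit = h @ params.values["w_hp"] + params.values["b_hp"]
    return _sigmoid(np.asarray(logit, dtype=float))


def forward_batch(params: NetworkParameters, observations: np.ndarray, keep_cache: bool = False):
    """Run a batch of sequences; returns (predictions, hidden_states[, caches]).

    ``observations`` is (B, T); predictions is (B, T) with p_t emitted
    after consuming x_t; hidden_states is (B, T, N).
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    B, T = obs.shape
    N = params.n_units
    h = np.zeros((B, N))
    hidden = np.empty((B, T, N))
    caches = [] if keep_cache else None
    for t in range(T):
        h, cache = _step_with_cache(params, h, obs[:, t])
        hidden[:, t] = h
        if keep_cache:
            caches.append(cache)
    logits = hidden @ params.values["w_hp"] + params.values["b_hp"]
    predictions = _sigmoid(logits)
    if keep_cache:
        return predictions, hidden, caches
    return predictions, hidden


def run_network(params: NetworkParameters, sequence) -> AgentTrace:
    """Run one network on one sequence, recording hidden states and Eq.-style log likelihood."""
    from .environments import GeneratedSequence

    x = sequence.observations if isinstance(sequence, GeneratedSequence) else np.asarray(sequence)
    x = x.astype(np.int64)
    predictions, hidden = forward_batch(params, x[None, :])
    p = predictions[0]
    ll = float(np.log(x[1:] * p[:-1] + (1 - x[1:]) * (1 - p[:-1])).sum())
    return AgentTrace(predictions=p, log_likelihood=ll, hidden_states=hidden[0])
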