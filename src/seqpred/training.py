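"""Self-supervised training of the recurrent networks.

Networks are trained to minimise the binary cross-entropy between the
prediction p_t and the next observation x_{t+1}, summed over
t = 0..T-2 (the final prediction has no target) and averaged over the
time steps and sequences of a minibatch.  Gradients are computed by
backpropagation through time over full sequences, implemented directly in
numpy (exactness is checked against central finite differences in the
test suite), and applied with Adam (beta1 = 0.9, beta2 = 0.999,
eps = 1e-8) at the initial step size eta0 selected per environment /
architecture / size.  One gradient update is made per minibatch and the
dataset is traversed once, after shuffling with the agent's own seed.

For the ``frozen_recurrence`` architecture only the output weights and
bias receive gradients, so no backpropagation through the recurrent
dynamics is needed; for ``no_lateral`` the off-diagonal gradient entries
are masked so the recurrent matrices stay diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import NetworkParameters, forward_batch

__all__ = ["TrainerConfig", "TrainingResult", "loss_and_gradients", "train_network"]


@dataclass(frozen=True)
class TrainerConfig:
    learning_rate: float = 0.05  # eta0; overridden by the hyperparameter table in practice
    minibatch_size: int = 20
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class TrainingResult:
    params: NetworkParameters
    loss_curve: np.ndarray  # minibatch cross-entropy (mean per scored step)


def loss_and_gradients(
    params: NetworkParameters, observations: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean per-step cross-entropy on a minibatch and its parameter gradients.

    Gradients are returned for every parameter of the architecture
    (trainability masks are applied by the optimiser, except the
    structural no-lateral mask which is applied here).
    """
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    B, T = obs.shape
    if T < 2:
        raise ValueError("sequences must have at least 2 observations to score a prediction")
    v = params.values
    N = params.n_units
    scale = 1.0 / (B * (T - 1))

    predictions, hidden, caches = forward_batch(params, obs, keep_cache=True)
    p = predictions[:, :-1]
    x_next = obs[:, 1:]
    lik = x_next * p + (1.0 - x_next) * (1.0 - p)
    loss = -np.log(lik).sum() * scale

    grads = {k: np.zeros_like(v[k]) for k in params.keys}
    # d(loss)/d(logit_t) for scored steps; zero for the last prediction
    dlogit = np.zeros((B, T))
    dlogit[:, :-1] = (p - x_next) * scale

    w_hp = v["w_hp"]
    gated = params.arch != "no_gating"
    if params.arch == "frozen_recurrence":
        # Output parameters do not influence the dynamics: no BPTT needed.
        grads["w_hp"] = np.einsum("bt,btn->n", dlogit, hidden)
        grads["b_hp"] = np.asarray(dlogit.sum())
        return loss, grads

    grads["w_hp"] = np.einsum("bt,btn->n", dlogit, hidden)
    grads["b_hp"] = np.asarray(dlogit.sum())
    carry = np.zeros((B, N))  # dL/dh_t flowing from the future
    for t in range(T - 1, -1, -1):
        h_prev, x, r, z, s, c = caches[t]
        g = carry + dlogit[:, t][:, None] * w_hp
        if gated:
            dz = g * (h_prev - c)
            da_z = dz * z * (1.0 - z)
            dc = g * (1.0 - z)
            da_c = dc * (1.0 - c * c)
            dr = da_c * s
            da_r = dr * r * (1.0 - r)
            ds = da_c * r
            grads["w_xh"] += (x * da_c).sum(axis=0)
            grads["b_xh"] += da_c.sum(axis=0)
            grads["b_hh"] += da_c.sum(axis=0)
            grads["w_xr"] += (x * da_r).sum(axis=0)
            grads["b_xr"] += da_r.sum(axis=0)
            grads["b_hr"] += da_r.sum(axis=0)
            grads["w_xz"] += (x * da_z).sum(axis=0)
            grads["b_xz"] += da_z.sum(axis=0)
            grads["b_hz"] += da_z.sum(axis=0)
            grads["W_hh"] += h_prev.T @ ds
            grads["W_hr"] += h_prev.T @ da_r
            grads["W_hz"] += h_prev.T @ da_z
            carry = (
                g * z
                + ds @ v["W_hh"].T
                + da_r @ v["W_hr"].T
                + da_z @ v["W_hz"].T
            )
        else:
            da_c = g * (1.0 - c * c)
            grads["w_xh"] += (x * da_c).sum(axis=0)
            grads["b_xh"] += da_c.sum(axis=0)
            grads["b_hh"] += da_c.sum(axis=0)
            grads["W_hh"] += h_prev.T @ da_c
            carry = da_c @ v["W_hh"].T

    if params.arch == "no_lateral":
        eye = np.eye(N)
        for k in ("W_hr", "W_hz", "W_hh"):
            grads[k] *= eye
    return loss, grads


def train_network(
    params: NetworkParameters,
    training_sequences: np.ndarray,
    config: TrainerConfig,
    rng: np.random.Generator | None = None,
) -> TrainingResult:
    """Single-pass Adam training over minibatches of sequences.

    ``training_sequences`` is an (n_sequences, T) binary array; it is
    shuffled with ``rng`` and split into minibatches of
    ``config.minibatch_size``.  Raises on non-finite loss.
    """
    seqs = np.atleast_2d(np.asarray(training_sequences))
    rng = rng or np.random.default_rng()
    params = params.copy()
    trainable = params.trainable_keys
    m = {k: np.zeros_like(params.values[k]) for k in trainable}
    s = {k: np.zeros_like(params.values[k]) for k in trainable}
    losses = []
    step = 0
    order = rng.permutation(len(seqs))
    for start in range(0, len(seqs), config.minibatch_size):
        batch = seqs[order[start : start + config.minibatch_size]]
        loss, grads = loss_and_gradients(params, batch)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at minibatch {len(losses)} "
                f"(arch={params.arch}, N={params.n_units})"
            )
        losses.append(loss)
        step += 1
        bc1 = 1.0 - config.beta1**step
        bc2 = 1.0 - config.beta2**step
        for k in trainable:
            g = grads[k]
            m[k] = config.beta1 * m[k] + (1.0 - config.beta1) * g
            s[k] = config.beta2 * s[k] + (1.0 - config.beta2) * g * g
            update = config.learning_rate * (m[k] / bc1) / (np.sqrt(s[k] / bc2) + config.eps)
            params.values[k] = params.values[k] - update
    return TrainingResult(params=params, loss_curve=np.asarray(losses))
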