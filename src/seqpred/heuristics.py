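"""Delta-rule and leaky-count heuristic agents, and SGD fitting of their free parameter.

Four heuristics are implemented, the cross of

* estimated quantity: a single base rate (``unigram``) or the two
  transition probabilities p(0|0), p(1|1) (``bigram``), and
* update rule: the Rescorla-Wagner ``delta`` rule
  (p_hat <- p_hat + alpha * (x - p_hat), initialised at 0.5) or the
  ``leaky`` counting rule (n_k <- alpha * n_k + event indicator, with the
  Laplace-smoothed estimate p_hat = (n_1 + 1)/(n_1 + n_0 + 2)).

In the bigram variants the update is conditioned on the previous
observation, and the emitted prediction is p_hat(1|1) after a 1 and
1 - p_hat(0|0) after a 0.  The single free parameter alpha (learning rate
for delta, decay for leaky) is fitted by stochastic gradient descent on
the binary cross-entropy, with the exact gradient obtained by forward-mode
differentiation through the recursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environments import GeneratedSequence

__all__ = [
    "HeuristicParams",
    "SGDConfig",
    "AgentTrace",
    "run_heuristic",
    "heuristic_loss_and_grad",
    "fit_heuristic",
    "draw_initial_alpha",
]

RULES = ("delta", "leaky")
SCOPES = ("unigram", "bigram")

ALPHA_MIN = 1e-4
ALPHA_MAX = 1.0 - 1e-4


@dataclass(frozen=True)
class HeuristicParams:
    rule: str
    scope: str
    alpha: float

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        hi = 1.0 if self.rule == "leaky" else 1.0 - 1e-12
        if not 0.0 < self.alpha <= hi:
            raise ValueError(f"alpha={self.alpha} out of range for rule {self.rule!r}")


@dataclass(frozen=True)
class SGDConfig:
    """Plain SGD on alpha: learning rate 3e-3, minibatches of 20, one pass."""

    learning_rate: float = 3e-3
    minibatch_size: int = 20
    n_epochs: int = 1


@dataclass
class AgentTrace:
    """Per-step predictions of any agent; p_t = P(x_{t+1}=1 | x_0..x_t).

    ``hidden_states`` is None for non-network agents.  The pre-sequence
    reference prediction is 0.5 (used as p_{-1} by the learning-rate
    analysis).  ``log_likelihood`` sums log-likelihood terms over
    t = 0..T-2, scoring p_t against x_{t+1}.
    """

    predictions: np.ndarray
    log_likelihood: float | np.ndarray
    hidden_states: np.ndarray | None = None
    prior_prediction: float = 0.5


def _log_likelihood(predictions: np.ndarray, observations: np.ndarray) -> np.ndarray:
    p = predictions[..., :-1]
    x = observations[..., 1:]
    return np.log(x * p + (1 - x) * (1 - p)).sum(axis=-1)


def _forward(rule: str, scope: str, alpha: float, x: np.ndarray, with_grad: bool):
    """Predictions p_t (and, optionally, dp_t/dalpha) for one sequence.

    Forward-mode differentiation: the tangent of every state variable with
    respect to alpha is propagated alongside the value.
    """
    T = x.size
    p_out = np.empty(T)
    d_out = np.empty(T) if with_grad else None
    a = alpha
    if scope == "unigram":
        if rule == "delta":
            p, dp = 0.5, 0.0
            for t in range(T):
                dp = dp + (x[t] - p) - a * dp
                p = p + a * (x[t] - p)
                p_out[t] = p
                if with_grad:
                    d_out[t] = dp
        else:
            n0 = n1 = 0.0
            dn0 = dn1 = 0.0
            for t in range(T):
                dn0, dn1 = n0 + a * dn0, n1 + a * dn1
                n0 = a * n0 + (1 - x[t])
                n1 = a * n1 + x[t]
                denom = n0 + n1 + 2.0
                p_out[t] = (n1 + 1.0) / denom
                if with_grad:
                    d_out[t] = (dn1 * denom - (n1 + 1.0) * (dn0 + dn1)) / denom**2
    else:
        # bigram rules update on observed pairs (x_{t}, x_{t+1}) only: the first
        # observation initialises the context without triggering an update
        if rule == "delta":
            p00 = p11 = 0.5
            d00 = d11 = 0.0
            prev = None
            for t in range(T):
                if prev == 1:
                    d11 = d11 + (x[t] - p11) - a * d11
                    p11 = p11 + a * (x[t] - p11)
                elif prev == 0:
                    d00 = d00 + ((1 - x[t]) - p00) - a * d00
                    p00 = p00 + a * ((1 - x[t]) - p00)
                prev = x[t]
                if prev == 1:
                    p_out[t] = p11
                    if with_grad:
                        d_out[t] = d11
                else:
                    p_out[t] = 1.0 - p00
                    if with_grad:
                        d_out[t] = -d00
        else:
            n = np.zeros(4)  # n00, n10, n01, n11 (n_{new|prev})
            dn = np.zeros(4)
            prev = None
            for t in range(T):
                if prev is not None:
                    dn = n + a * dn
                    n = a * n
                    n[2 * prev + x[t]] += 1.0
                prev = x[t]
                if prev == 1:
                    num, den = n[3] + 1.0, n[3] + n[2] + 2.0
                    dnum, dden = dn[3], dn[3] + dn[2]
                    p_out[t] = num / den
                    if with_grad:
                        d_out[t] = (dnum * den - num * dden) / den**2
                else:
                    num, den = n[0] + 1.0, n[0] + n[1] + 2.0
                    dnum, dden = dn[0], dn[0] + dn[1]
                    p_out[t] = 1.0 - num / den
                    if with_grad:
                        d_out[t] = -(dnum * den - num * dden) / den**2
    return p_out, d_out


def run_heuristic(params: HeuristicParams, sequence: GeneratedSequence | np.ndarray) -> AgentTrace:
    """Run one heuristic agent on one sequence."""
    x = sequence.observations if isinstance(sequence, GeneratedSequence) else np.asarray(sequence)
    x = x.astype(np.int64)
    p, _ = _forward(params.rule, params.scope, params.alpha, x, with_grad=False)
    return AgentTrace(predictions=p, log_likelihood=float(_log_likelihood(p, x)))


def heuristic_loss_and_grad(
    rule: str, scope: str, alpha: float, sequences: np.ndarray
) -> tuple[float, float]:
    """Mean cross-entropy per scored step over a batch, and d(loss)/d(alpha)."""
    seqs = np.atleast_2d(np.asarray(sequences)).astype(np.int64)
    total_loss = 0.0
    total_grad = 0.0
    n_terms = 0
    for x in seqs:
        p, dp = _forward(rule, scope, alpha, x, with_grad=True)
        xt, pt, dpt = x[1:], p[:-1], dp[:-1]
        # guard against float collapse of p onto {0, 1} at extreme alpha
        lik = np.clip(xt * pt + (1 - xt) * (1 - pt), 1e-12, None)
        total_loss -= np.log(lik).sum()
        total_grad -= ((2 * xt - 1) * dpt / lik).sum()
        n_terms += xt.size
    return total_loss / n_terms, total_grad / n_terms


def draw_initial_alpha(rule: str, rng: np.random.Generator) -> float:
    """Initial alpha: r ~ log-uniform on [1e-2.5, 1e-0.5]; alpha = r (delta) or exp(-r) (leaky)."""
    r = 10.0 ** rng.uniform(-2.5, -0.5)
    return float(r) if rule == "delta" else float(np.exp(-r))


def fit_heuristic(
    rule: str,
    scope: str,
    training_sequences: np.ndarray,
    sgd: SGDConfig | None = None,
    rng: np.random.Generator | None = None,
) -> HeuristicParams:
    """Fit alpha by SGD on the cross-entropy over the training dataset.

    The dataset is shuffled, split into minibatches, and traversed once
    (the loss converges within a single pass at the dataset sizes used
    here).  After each step alpha is projected to [1e-4, 1 - 1e-4] to keep
    the recursion well defined.
    """
    seqs = np.atleast_2d(np.asarray(training_sequences)).astype(np.int64)
    if seqs.size == 0:
        raise ValueError("empty training dataset")
    sgd = sgd or SGDConfig()
    rng = rng or np.random.default_rng()
    alpha = draw_initial_alpha(rule, rng)
    for _ in range(sgd.n_epochs):
        order = rng.permutation(len(seqs))
        for start in range(0, len(seqs), sgd.minibatch_size):
            batch = seqs[order[start : start + sgd.minibatch_size]]
            _, grad = heuristic_loss_and_grad(rule, scope, alpha, batch)
            alpha = float(np.clip(alpha - sgd.learning_rate * grad, ALPHA_MIN, ALPHA_MAX))
    return HeuristicParams(rule=rule, scope=scope, alpha=alpha)
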