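"""Constrained activity perturbations testing the causal role of read precision.

A perturbation vector q added to the recurrent state must (i) leave the
network's current prediction unchanged (q . w_pred = 0), (ii) move the
read precision by a prescribed amount (q . w_prec = delta), and (iii)
have a fixed intensity (||q|| = c).  It is built from two components that
both preserve the prediction: a deterministic one along the precision
direction within the null space of w_pred, and a random one that affects
neither quantity, scaled to reach the target norm:

1. Q  = null space of w_pred (dimension N - 1);
2. q_psi = orthogonal projection of w_prec onto Q;
3. beta_psi = delta / (q_psi . w_prec);
4. R  = null space of q_psi within Q (dimension N - 2);
5. q_r = random unit vector in R;
6. beta_r = sqrt(c^2 - beta_psi^2 ||q_psi||^2)  (feasibility requires the
   radicand to be nonnegative);
7. q = beta_psi q_psi + beta_r q_r.

The experiment measures, at probe time points, the difference between the
perturbed and unperturbed effective learning rate at the next step, per
level of the precision change delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from ..networks import NetworkParameters, forward_batch, network_output, network_step
from .learning_rate import DEGENERATE_TOL
from .readout import ReadoutModel

__all__ = ["PerturbationSpec", "make_perturbation", "perturbation_experiment"]

_TOL = 1e-10


@dataclass(frozen=True)
class PerturbationSpec:
    """Probe design: delta levels symmetric around 0, fixed norm c.

    With ``norm=None`` the norm defaults to 0.1 x the median hidden-state
    norm over probe points, and with ``delta_levels=None`` the five levels
    span +/- 1 SD of the read precision; both resolved at run time and
    recorded in the experiment output.
    """

    delta_levels: tuple[float, ...] | None = None
    norm: float | None = None
    n_probes: int = 1000
    n_sequences: int = 300
    t_min: int = 10  # probe times drawn uniformly from [t_min, T-2]


def make_perturbation(
    w_pred: np.ndarray,
    w_prec: np.ndarray,
    delta: float,
    c: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One random perturbation vector satisfying the three constraints."""
    w_pred = np.asarray(w_pred, dtype=float)
    w_prec = np.asarray(w_prec, dtype=float)
    N = w_pred.size
    if N < 3:
        raise ValueError("perturbation construction needs at least 3 units")
    Q = null_space(w_pred[None, :])  # (N, N-1)
    q_psi = Q @ (Q.T @ w_prec)
    qn2 = float(q_psi @ w_prec)
    if qn2 < _TOL:
        raise ValueError("degenerate: precision vector collinear with prediction vector")
    beta_psi = delta / qn2
    radicand = c**2 - beta_psi**2 * float(q_psi @ q_psi)
    if radicand < -_TOL * max(c**2, 1.0):
        raise ValueError(
            f"infeasible perturbation: norm c={c} too small for requested delta={delta}"
        )
    beta_r = np.sqrt(max(radicand, 0.0))
    R = null_space(np.vstack([w_pred, q_psi]))  # (N, N-2)
    coeffs = rng.standard_normal(R.shape[1])
    coeffs /= np.linalg.norm(coeffs)
    q_r = R @ coeffs
    return beta_psi * q_psi + beta_r * q_r


def perturbation_experiment(
    params: NetworkParameters,
    readout: ReadoutModel,
    sequences: np.ndarray,
    spec: PerturbationSpec,
    rng: np.random.Generator,
) -> dict:
    """Per-delta mean change in the next-step effective learning rate.

    For each probe point (sequence, t): the unperturbed learning rate at
    t + 1 is computed from the baseline run; then q is added to h_t, one
    step is taken with x_{t+1}, and the perturbed learning rate is
    measured.  Probe points whose unperturbed learning rate is degenerate
    (|x_{t+1} - p_t| below tolerance) are resampled.  Because
    q . w_pred = 0 the prediction at t, and hence the prediction error at
    t + 1, is unchanged by construction.
    """
    seqs = np.atleast_2d(np.asarray(sequences))
    n_seq, T = seqs.shape
    w_pred = params.values["w_hp"]
    w_prec = readout.weights

    predictions, hidden = forward_batch(params, seqs)

    # candidate probe points with a non-degenerate unperturbed learning rate
    valid_t = np.arange(spec.t_min, T - 1)
    cand_seq = rng.integers(0, n_seq, size=4 * spec.n_probes)
    cand_t = valid_t[rng.integers(0, valid_t.size, size=4 * spec.n_probes)]
    denom = seqs[cand_seq, cand_t + 1] - predictions[cand_seq, cand_t]
    keep = np.abs(denom) >= DEGENERATE_TOL
    if keep.sum() < spec.n_probes:
        raise RuntimeError("could not draw enough non-degenerate probe points")
    sel = np.flatnonzero(keep)[: spec.n_probes]
    probe_seq, probe_t = cand_seq[sel], cand_t[sel]

    h0 = hidden[probe_seq, probe_t]  # (P, N)
    x_next = seqs[probe_seq, probe_t + 1].astype(float)
    p_t = predictions[probe_seq, probe_t]
    p_next = predictions[probe_seq, probe_t + 1]
    alpha_unpert = (p_next - p_t) / (x_next - p_t)

    c = spec.norm
    if c is None:
        c = 0.1 * float(np.median(np.linalg.norm(h0, axis=1)))
    levels = spec.delta_levels
    if levels is None:
        # span +-1 SD of the read precision, capped at the feasible range:
        # |delta| <= c * ||q_psi|| given the norm constraint
        sd_prec = float(np.std(readout.predict(hidden)))
        u = w_pred / np.linalg.norm(w_pred)
        q_psi_norm = float(np.linalg.norm(w_prec - (w_prec @ u) * u))
        delta_max = min(sd_prec, 0.9 * c * q_psi_norm)
        levels = tuple(np.linspace(-delta_max, delta_max, 5))

    mean_changes = []
    per_level_changes = []
    for delta in levels:
        q = np.stack(
            [make_perturbation(w_pred, w_prec, delta, c, rng) for _ in range(len(probe_seq))]
        )
        h_pert = h0 + q
        h1 = network_step(params, h_pert, x_next)
        p1 = network_output(params, h1)
        # q is orthogonal to w_pred, so the prediction at t is unchanged
        alpha_pert = (p1 - p_t) / (x_next - p_t)
        change = alpha_pert - alpha_unpert
        per_level_changes.append(change)
        mean_changes.append(float(change.mean()))

    return {
        "delta_levels": np.asarray(levels),
        "norm": c,
        "mean_change": np.asarray(mean_changes),
        "changes": np.stack(per_level_changes),  # (n_levels, n_probes)
        "probe_seq": probe_seq,
        "probe_t": probe_t,
    }
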