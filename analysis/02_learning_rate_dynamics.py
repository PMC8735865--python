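#!/usr/bin/env python
"""Effective learning rate around change points locked at fixed times.

Generates unigram sequences whose change points all occur at the same time
steps, runs the optimal observer, trained networks, and fitted heuristics,
and records the sequence-averaged effective learning rate per time step.
The gated networks and the optimal observer show transient peaks after
each change; the delta rule is flat by construction.  Writes
results/learning_rate/learning_rate_curves.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from seqpred.analyses import effective_learning_rate
from seqpred.environments import EnvironmentConfig, generate_locked_batch
from seqpred.heuristics import SGDConfig, fit_heuristic, run_heuristic
from seqpred.hyperparameters import HEURISTIC_SGD_LEARNING_RATE
from seqpred.networks import forward_batch
from seqpred.optimal import run_optimal_batch
from seqpred.workflows import make_training_data, train_group

LOCKED_TIMES = [75, 150, 225, 300]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/learning_rate"))
    args = ap.parse_args()

    reps = max(2, round(20 * args.scale))
    n_seq = max(200, round(10_000 * args.scale))
    base = args.seed * 1000

    cfg = EnvironmentConfig("unigram")
    locked = generate_locked_batch(EnvironmentConfig("unigram", seed=base + 5), LOCKED_TIMES, n_seq)
    obs = np.stack([s.observations for s in locked])
    train = make_training_data("unigram", 160, seed=base + 1)

    curves = {}
    opt = run_optimal_batch(obs, cfg)
    curves["optimal"] = effective_learning_rate(opt.predictions, obs).masked_mean(axis=0)

    for arch in ("gated", "no_gating", "no_lateral", "frozen_recurrence"):
        per_net = []
        for result in train_group("unigram", arch, 11, reps, train, base + 3):
            preds, _ = forward_batch(result.params, obs)
            per_net.append(effective_learning_rate(preds, obs).masked_mean(axis=0))
        curves[arch] = np.nanmean(per_net, axis=0)

    for rule in ("delta", "leaky"):
        rng = np.random.default_rng([base + 4, 0])
        fitted = fit_heuristic(rule, "unigram", train,
                               SGDConfig(learning_rate=HEURISTIC_SGD_LEARNING_RATE), rng)
        preds = np.stack([run_heuristic(fitted, x).predictions for x in obs[:500]])
        curves[rule] = effective_learning_rate(preds, obs[:500]).masked_mean(axis=0)

    frame = pd.DataFrame({"t": np.arange(obs.shape[1]), **curves})
    args.out.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out / "learning_rate_curves.csv", index=False)

    for name, curve in curves.items():
        t0 = LOCKED_TIMES[1]
        base_lr = np.nanmean(curve[t0 - 40 : t0])
        peak = np.nanmax(curve[t0 : t0 + 10])
        print(f"{name:>20s}: baseline {base_lr:.3f}, post-change peak {peak:.3f} "
              f"({'adaptive' if peak > 1.3 * base_lr else 'flat-ish'})")


if __name__ == "__main__":
    main()
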