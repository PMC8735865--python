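#!/usr/bin/env python
"""Prediction performance in the changing unigram environment.

Trains the four recurrent architectures (N = 11) and the unigram
heuristics on a shared dataset, evaluates every agent as % of optimal log
likelihood on a shared test set, and runs Welch t-tests of the gated group
against every other group.  Writes results/performance_unigram/
{performance.csv, tests.json}.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from seqpred.analyses import group_statistics
from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.heuristics import SGDConfig, fit_heuristic, run_heuristic
from seqpred.hyperparameters import HEURISTIC_SGD_LEARNING_RATE
from seqpred.networks import forward_batch
from seqpred.optimal import run_optimal_batch
from seqpred.analyses.performance import chance_log_likelihood, percent_optimal, trace_log_likelihood
from seqpred.workflows import make_training_data, train_group

ARCHS = ("gated", "no_gating", "no_lateral", "frozen_recurrence")
HEURISTICS = (("delta", "unigram"), ("leaky", "unigram"))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/performance_unigram"))
    args = ap.parse_args()

    reps = max(2, round(20 * args.scale))
    n_test = max(50, round(1000 * args.scale))
    base = args.seed * 1000

    cfg = EnvironmentConfig("unigram")
    train = make_training_data("unigram", 160, seed=base + 1)
    test = generate_batch(EnvironmentConfig("unigram", seed=base + 2), n_test)
    L_optimal = float(np.sum(run_optimal_batch(test, cfg).log_likelihood))
    L_chance = chance_log_likelihood(test)

    rows = []
    for arch in ARCHS:
        for rep, result in enumerate(train_group("unigram", arch, 11, reps, train, base + 3)):
            preds, _ = forward_batch(result.params, test)
            L = float(np.sum(trace_log_likelihood(preds, test)))
            rows.append({"agent": arch, "replicate": rep,
                         "percent_optimal": percent_optimal(L, L_optimal, L_chance)})
    for rule, scope in HEURISTICS:
        for rep in range(reps):
            rng = np.random.default_rng([base + 4, rep])
            fitted = fit_heuristic(rule, scope, train,
                                   SGDConfig(learning_rate=HEURISTIC_SGD_LEARNING_RATE), rng)
            preds = np.stack([run_heuristic(fitted, x).predictions for x in test])
            L = float(np.sum(trace_log_likelihood(preds, test)))
            rows.append({"agent": f"{rule}_{scope}", "replicate": rep,
                         "percent_optimal": percent_optimal(L, L_optimal, L_chance)})

    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "performance.csv", index=False)

    gated = table[table.agent == "gated"].percent_optimal.to_numpy()
    tests = {}
    for agent in table.agent.unique():
        if agent == "gated":
            continue
        other = table[table.agent == agent].percent_optimal.to_numpy()
        tests[agent] = group_statistics(gated, other, "welch_two_sided")
    (args.out / "tests.json").write_text(json.dumps(tests, indent=2, default=float))

    summary = table.groupby("agent").percent_optimal.agg(["mean", "max"])
    print(summary.round(2))
    print(f"\ngated mean {gated.mean():.2f} % of optimal over {reps} seeds; "
          f"all pairwise Welch p-values: "
          f"{ {k: round(v['p_value'], 6) for k, v in tests.items()} }")


if __name__ == "__main__":
    main()
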