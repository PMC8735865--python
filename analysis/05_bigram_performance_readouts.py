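#!/usr/bin/env python
"""Performance and internal representations in the changing bigram environment.

Trains the four architectures and the four heuristics in the bigram
environment with independent change points, tabulates % of optimal log
likelihood and the ablation drops relative to the gated group, and fits
the four linear readouts (log odds of the posterior mean and log precision
for each of p(0|0), p(1|1)) from gated recurrent activity.  Writes
results/bigram/{performance.csv, readouts.csv}.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from seqpred.analyses import evaluate_readout, fit_readout
from seqpred.analyses.performance import chance_log_likelihood, percent_optimal, trace_log_likelihood
from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.heuristics import SGDConfig, fit_heuristic, run_heuristic
from seqpred.hyperparameters import HEURISTIC_SGD_LEARNING_RATE
from seqpred.networks import forward_batch
from seqpred.optimal import run_optimal_batch
from seqpred.workflows import make_training_data, train_group

ARCHS = ("gated", "no_gating", "no_lateral", "frozen_recurrence")
HEURISTICS = (("delta", "unigram"), ("leaky", "unigram"), ("delta", "bigram"), ("leaky", "bigram"))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/bigram"))
    args = ap.parse_args()

    reps = max(2, round(20 * args.scale))
    n_test = max(50, round(1000 * args.scale))
    base = args.seed * 1000
    cfg = EnvironmentConfig("bigram_independent")

    train = make_training_data("bigram_independent", 400, seed=base + 11)
    test = generate_batch(EnvironmentConfig("bigram_independent", seed=base + 12), n_test)
    L_optimal = float(np.sum(run_optimal_batch(test, cfg).log_likelihood))
    L_chance = chance_log_likelihood(test)

    rows, groups = [], {}
    for arch in ARCHS:
        groups[arch] = train_group("bigram_independent", arch, 11, reps, train, base + 13)
        for rep, result in enumerate(groups[arch]):
            preds, _ = forward_batch(result.params, test)
            L = float(np.sum(trace_log_likelihood(preds, test)))
            rows.append({"agent": arch, "replicate": rep,
                         "percent_optimal": percent_optimal(L, L_optimal, L_chance)})
    for rule, scope in HEURISTICS:
        for rep in range(reps):
            rng = np.random.default_rng([base + 16, rep])
            fitted = fit_heuristic(rule, scope, train,
                                   SGDConfig(learning_rate=HEURISTIC_SGD_LEARNING_RATE), rng)
            preds = np.stack([run_heuristic(fitted, x).predictions for x in test])
            L = float(np.sum(trace_log_likelihood(preds, test)))
            rows.append({"agent": f"{rule}_{scope}", "replicate": rep,
                         "percent_optimal": percent_optimal(L, L_optimal, L_chance)})

    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "performance.csv", index=False)

    means = table.groupby("agent").percent_optimal.mean()
    print(means.round(2))
    for arch in ARCHS[1:]:
        print(f"drop {arch:>20s}: {means[arch] - means['gated']:+.1f} points")

    # readouts of the latent bigram estimates and their precision
    ro_train = generate_batch(EnvironmentConfig("bigram_independent", seed=base + 14), 900)
    ro_test = generate_batch(EnvironmentConfig("bigram_independent", seed=base + 15), 100)
    opt_train = run_optimal_batch(ro_train, cfg)
    opt_test = run_optimal_batch(ro_test, cfg)
    logodds = lambda m: np.log(m / (1 - m))
    ro_rows = []
    for rep, result in enumerate(groups["gated"]):
        _, h_train = forward_batch(result.params, ro_train)
        _, h_test = forward_batch(result.params, ro_test)
        for k, name in ((0, "p00"), (1, "p11")):
            m_est = fit_readout(h_train, logodds(opt_train.means[:, k, :]))
            m_prec = fit_readout(h_train, opt_train.log_precisions[:, k, :])
            ro_rows.append({
                "replicate": rep, "latent": name,
                "estimate_r": evaluate_readout(m_est, h_test, logodds(opt_test.means[:, k, :])),
                "precision_r": evaluate_readout(
                    m_prec, h_test, opt_test.log_precisions[:, k, :]
                ),
            })
    ro_table = pd.DataFrame(ro_rows)
    ro_table.to_csv(args.out / "readouts.csv", index=False)
    print("\nreadout medians over networks:")
    print(ro_table.groupby("latent")[["estimate_r", "precision_r"]].median().round(3))


if __name__ == "__main__":
    main()
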