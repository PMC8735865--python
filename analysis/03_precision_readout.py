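#!/usr/bin/env python
"""Linear readout of estimation precision from gated recurrent activity.

For each trained gated network: fit an OLS readout from the 11 hidden
activations to the optimal observer's log precision (psi = -log posterior
SD), evaluate it on held-out sequences, correlate the read precision with
the next-step effective learning rate, and measure the mutual information
between read precision and the network's own prediction (compared across
architectures and with the optimal observer).  Writes
results/precision_readout/readout.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from seqpred.analyses import (
    effective_learning_rate,
    evaluate_readout,
    fit_readout,
    mutual_information,
)
from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.networks import forward_batch
from seqpred.optimal import run_optimal_batch
from seqpred.workflows import make_training_data, train_group


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.25)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/precision_readout"))
    args = ap.parse_args()

    reps = max(2, round(20 * args.scale))
    base = args.seed * 1000
    cfg = EnvironmentConfig("unigram")

    train = make_training_data("unigram", 160, seed=base + 1)
    ro_train = generate_batch(EnvironmentConfig("unigram", seed=base + 4), 900)
    ro_test = generate_batch(EnvironmentConfig("unigram", seed=base + 5), 100)
    corr_seqs = generate_batch(EnvironmentConfig("unigram", seed=base + 6), 300)
    opt_train = run_optimal_batch(ro_train, cfg)
    opt_test = run_optimal_batch(ro_test, cfg)
    psi_train = opt_train.log_precisions[:, 0, :]
    psi_test = opt_test.log_precisions[:, 0, :]

    rows = []
    for arch in ("gated", "no_gating"):
        for rep, result in enumerate(train_group("unigram", arch, 11, reps, train, base + 3)):
            _, h_train = forward_batch(result.params, ro_train)
            _, h_test = forward_batch(result.params, ro_test)
            model = fit_readout(h_train, psi_train)
            acc = evaluate_readout(model, h_test, psi_test)
            preds, hidden = forward_batch(result.params, corr_seqs)
            lr = effective_learning_rate(preds, corr_seqs)
            read = model.predict(hidden)
            valid = lr.valid[:, 1:].ravel()
            r_lr = stats.pearsonr(
                read[:, :-1].ravel()[valid], lr.alpha[:, 1:].ravel()[valid]
            ).statistic
            mi = mutual_information(read, preds)
            rows.append({"arch": arch, "replicate": rep, "readout_r": acc,
                         "precision_lr_r": r_lr, "mi_precision_prediction": mi})

    # the optimal observer's own quantities, as reference
    lr_opt = effective_learning_rate(opt_test.predictions, ro_test)
    valid = lr_opt.valid[:, 1:].ravel()
    r_opt = stats.pearsonr(
        psi_test[:, :-1].ravel()[valid], lr_opt.alpha[:, 1:].ravel()[valid]
    ).statistic
    mi_opt = mutual_information(psi_test, opt_test.predictions)

    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "readout.csv", index=False)

    med = table.groupby("arch").median(numeric_only=True)
    print(med.round(3))
    print(f"\noptimal reference: precision/learning-rate r = {r_opt:.3f}, "
          f"MI(precision, prediction) = {mi_opt:.2f} nats")


if __name__ == "__main__":
    main()
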