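#!/usr/bin/env python
"""Performance as a function of network size, with the vanilla-RNN power law.

Sweeps a log-spaced grid of sizes N for each architecture in the unigram
environment (hyperparameters resolve to the nearest tabulated N in log
space), then fits (100 - p) = c (1/N)^a to the no-gating results and
extrapolates.  At full print scale this uses 20 networks at ~12 sizes up
to N = 1000; the default here is heavily reduced.  Writes
results/complexity/{sweep.csv, power_law.json}.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from seqpred.analyses.complexity import complexity_sweep, fit_power_law, log_spaced_sizes
from seqpred.environments import EnvironmentConfig, generate_batch
from seqpred.workflows import make_training_data


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--scale", type=float, default=0.1)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--archs", nargs="*", default=["gated", "no_gating"])
    ap.add_argument("--n-points", type=int, default=6)
    ap.add_argument("--out", type=Path, default=Path("results/complexity"))
    args = ap.parse_args()

    reps = max(2, round(20 * args.scale))
    n_test = max(100, round(1000 * args.scale))
    base = args.seed * 1000

    train = make_training_data("unigram", 160, seed=base + 1)
    test = generate_batch(EnvironmentConfig("unigram", seed=base + 2), n_test)
    grid = log_spaced_sizes(args.n_points, 2, 45)

    tables = []
    for arch in args.archs:
        tables.append(
            complexity_sweep(arch, EnvironmentConfig("unigram"), grid, reps, train, test,
                             seed=base + 3)
        )
    import pandas as pd

    sweep = pd.concat(tables, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    sweep.to_csv(args.out / "sweep.csv", index=False)

    summary = sweep[~sweep.failed].groupby(["arch", "n_units"]).percent_optimal.mean()
    print(summary.round(2))

    if "no_gating" in args.archs:
        means = summary.loc["no_gating"]
        fit = fit_power_law(means.index.to_numpy(), means.to_numpy())
        (args.out / "power_law.json").write_text(json.dumps(
            {"coefficient": fit.coefficient, "exponent": fit.exponent,
             "r_squared": fit.r_squared,
             "predicted_percent_at_1000": fit.predict_percent(1000)}, indent=2))
        print(f"\nno-gating power law: (100-p) = {fit.coefficient:.1f} (1/N)^{fit.exponent:.2f}, "
              f"R^2 = {fit.r_squared:.1f} %; extrapolated p(N=1000) = "
              f"{fit.predict_percent(1000):.1f} %")


if __name__ == "__main__":
    main()
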