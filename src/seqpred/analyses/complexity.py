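"""Performance as a function of network size, and the power-law summary.

The sweep trains ``replicates`` networks per size N on fresh data and
evaluates the % of optimal log likelihood on a shared test set.  The slow
growth of the vanilla (no-gating) networks' performance with N is
summarised by the power law (100 - p) = c (1/N)^a, fitted by least
squares on (log N, log(100 - p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..environments import EnvironmentConfig
from ..hyperparameters import load_hyperparameters
from ..networks import forward_batch, initialize_network
from ..optimal import run_optimal_batch
from ..training import TrainerConfig, train_network
from .performance import chance_log_likelihood, percent_optimal, trace_log_likelihood

__all__ = ["PowerLawFit", "complexity_sweep", "fit_power_law", "log_spaced_sizes"]


@dataclass
class PowerLawFit:
    coefficient: float  # c
    exponent: float  # a
    r_squared: float  # of the log-log linear fit, in %

    def predict_percent(self, n_units) -> np.ndarray:
        """Predicted % of optimal at size N from the fitted law."""
        n = np.asarray(n_units, dtype=float)
        return 100.0 - self.coefficient * (1.0 / n) ** self.exponent


def log_spaced_sizes(n_points: int = 12, lo: int = 1, hi: int = 45) -> np.ndarray:
    """Equally spaced sizes in log space, rounded to unique integers."""
    return np.unique(np.round(np.geomspace(lo, hi, n_points)).astype(int))


def fit_power_law(n_values, percent_values) -> PowerLawFit:
    """Least-squares line on (log N, log(100 - p))."""
    n = np.asarray(n_values, dtype=float)
    p = np.asarray(percent_values, dtype=float)
    if np.any(p >= 100.0):
        raise ValueError("power-law fit requires all percent values < 100")
    x = np.log(n)
    y = np.log(100.0 - p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else 100.0
    return PowerLawFit(coefficient=float(np.exp(intercept)), exponent=float(-slope), r_squared=r2)


def complexity_sweep(
    arch: str,
    config: EnvironmentConfig,
    n_grid,
    replicates: int,
    train_sequences: np.ndarray,
    test_sequences: np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Train ``replicates`` networks per size and tabulate % of optimal.

    Hyperparameters resolve per size via the nearest tabulated N in log
    space.  Training failures are recorded (``failed`` flag) and excluded
    from the summary statistics by the caller.
    """
    opt = run_optimal_batch(test_sequences, config)
    L_optimal = float(np.sum(opt.log_likelihood))
    L_chance = chance_log_likelihood(test_sequences)

    rows = []
    for N in np.asarray(n_grid, dtype=int):
        hp = load_hyperparameters(config.structure, arch, int(N), nearest=True)
        for rep in range(replicates):
            rng = np.random.default_rng([seed, int(N), rep])
            params = initialize_network(arch, int(N), hp.sigma0_x, hp.sigma0_h, hp.mu0_diag, rng)
            try:
                result = train_network(
                    params, train_sequences, TrainerConfig(learning_rate=hp.eta0), rng
                )
                preds, _ = forward_batch(result.params, test_sequences)
                L = float(np.sum(trace_log_likelihood(preds, test_sequences)))
                pct = percent_optimal(L, L_optimal, L_chance)
                failed = False
            except FloatingPointError:
                pct, failed = np.nan, True
            rows.append(
                {"arch": arch, "n_units": int(N), "replicate": rep, "percent_optimal": pct,
                 "failed": failed}
            )
    return pd.DataFrame(rows)
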