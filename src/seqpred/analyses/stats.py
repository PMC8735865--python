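"""Group comparison statistics used across the analyses.

Modes:

* ``welch_two_sided`` / ``welch_one_sided`` — two independent samples
  t-test with Welch's correction (Satterthwaite degrees of freedom);
  the one-sided alternative is mean(a) > mean(b).
* ``paired_one_sided`` — paired t-test on differences (a - b > 0);
  zero-variance differences are flagged as degenerate.
* ``interaction_f`` — interaction F from a balanced two-factor linear
  model; each sample argument is a pair of arrays giving the two levels
  of the second factor within one level of the first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

__all__ = ["group_statistics", "welch_ci_halfwidth"]

MODES = ("welch_two_sided", "welch_one_sided", "paired_one_sided", "interaction_f")


def welch_ci_halfwidth(a, b, level: float = 0.95) -> float:
    """Half-width of the Welch t interval for mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    dof = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(stats.t.ppf(0.5 + level / 2, dof) * np.sqrt(va + vb))


def group_statistics(samples_a, samples_b, mode: str) -> dict:
    """Test statistic and p-value for the requested comparison mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    if mode == "interaction_f":
        (a1, a2), (b1, b2) = samples_a, samples_b
        cells = [np.asarray(c, dtype=float) for c in (a1, a2, b1, b2)]
        if any(c.size < 2 for c in cells):
            raise ValueError("each cell needs at least 2 samples")
        y = np.concatenate(cells)
        fa = np.repeat(["a", "a", "b", "b"], [c.size for c in cells])
        fb = np.repeat(["1", "2", "1", "2"], [c.size for c in cells])
        frame = pd.DataFrame({"y": y, "fa": fa, "fb": fb})
        table = sm.stats.anova_lm(ols("y ~ fa * fb", data=frame).fit(), typ=2)
        return {
            "statistic": float(table.loc["fa:fb", "F"]),
            "p_value": float(table.loc["fa:fb", "PR(>F)"]),
            "dof": (float(table.loc["fa:fb", "df"]), float(table.loc["Residual", "df"])),
        }

    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")

    if mode == "paired_one_sided":
        if a.size != b.size:
            raise ValueError("paired test requires equal sample sizes")
        diff = a - b
        if np.allclose(diff.var(ddof=1), 0.0):
            return {
                "statistic": np.inf if diff.mean() > 0 else (-np.inf if diff.mean() < 0 else 0.0),
                "p_value": np.nan,
                "degenerate": True,
            }
        res = stats.ttest_rel(a, b, alternative="greater")
        return {"statistic": float(res.statistic), "p_value": float(res.pvalue)}

    alternative = "two-sided" if mode == "welch_two_sided" else "greater"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "dof": float(res.df),
    }
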