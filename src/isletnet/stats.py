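"""Off-the-shelf statistical tests used by the report stage.

The bespoke computation (networks, null model) lives upstream; these are
thin wrappers over scipy / pingouin with the listwise-deletion and
degenerate-input conventions of the pipeline: complete pairs/rows only,
fewer observations than a test needs marks the result underpowered, and
zero-variance inputs return the analytically obvious answer instead of
NaN.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "stat_paired_t",
    "stat_wilcoxon_signed_rank",
    "stat_linear_regression",
    "stat_rm_anova_gg",
]

MIN_PAIRS = 3


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def stat_paired_t(x, y) -> dict:
    """Two-sided paired t-test; returns t, df, p, mean difference and 95% CI."""
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < MIN_PAIRS:
        return {"n": n, "underpowered": True, "t": None, "df": None, "p": None,
                "mean_diff": None, "ci95": None}
    diff = x - y
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean_diff == 0.0 else math.copysign(math.inf, mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
        ci = (mean_diff, mean_diff)
    else:
        res = sps.ttest_rel(x, y)
        t, p = float(res.statistic), float(res.pvalue)
        half = float(sps.t.ppf(0.975, df)) * sd / math.sqrt(n)
        ci = (mean_diff - half, mean_diff + half)
    return {"n": n, "underpowered": False, "t": t, "df": df, "p": p,
            "mean_diff": mean_diff, "ci95": ci}


def stat_wilcoxon_signed_rank(x, y) -> dict:
    """Two-sided Wilcoxon matched-pairs signed-rank test."""
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < MIN_PAIRS:
        return {"n": n, "underpowered": True, "w": None, "p": None,
                "median_diff": None}
    diff = x - y
    median_diff = float(np.median(diff))
    if np.all(diff == 0):
        return {"n": n, "underpowered": False, "w": 0.0, "p": 1.0,
                "median_diff": 0.0}
    res = sps.wilcoxon(x, y)
    return {"n": n, "underpowered": False, "w": float(res.statistic),
            "p": float(res.pvalue), "median_diff": median_diff}


def stat_linear_regression(x, y) -> dict:
    """Simple linear regression of y on x with R² and slope p-value."""
    x, y = _complete_pairs(x, y)
    n = len(x)
    if n < MIN_PAIRS:
        return {"n": n, "underpowered": True, "slope": None, "intercept": None,
                "r2": None, "p": None, "slope_ci95": None}
    if np.ptp(x) == 0:
        return {"n": n, "underpowered": False, "slope": float("nan"),
                "intercept": float("nan"), "r2": float("nan"), "p": float("nan"),
                "slope_ci95": None, "degenerate": True}
    res = sps.linregress(x, y)
    half = float(sps.t.ppf(0.975, n - 2)) * res.stderr if n > 2 else float("nan")
    return {"n": n, "underpowered": False, "slope": float(res.slope),
            "intercept": float(res.intercept), "r2": float(res.rvalue**2),
            "p": float(res.pvalue),
            "slope_ci95": (float(res.slope - half), float(res.slope + half))}


def stat_rm_anova_gg(matrix, condition_names=None) -> dict:
    """Repeated-measures one-way ANOVA with Geisser–Greenhouse correction.

    ``matrix`` is subjects × conditions (here: islets × network types);
    rows containing NaN are dropped listwise.  The Geisser–Greenhouse
    epsilon rescales the degrees of freedom; Tukey HSD pairwise
    comparisons of the condition means are attached.
    """
    m = np.asarray(matrix, dtype=float)
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if condition_names is None:
        condition_names = [f"cond{i}" for i in range(k)]
    if n < MIN_PAIRS or k < 2:
        return {"n": n, "underpowered": True, "F": None, "df": None, "p": None,
                "eps": None, "tukey": None}
    if np.allclose(m, m[:, [0]]):
        # Identical values in every condition: no effect by construction.
        return {"n": n, "underpowered": False, "F": 0.0,
                "df": (float(k - 1), float((k - 1) * (n - 1))), "p": 1.0,
                "eps": 1.0, "tukey": []}
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(condition_names, n),
            "value": m.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="condition", subject="subject",
        correction=True, detailed=False,
    )
    row = aov.iloc[0]
    eps = float(row["eps"])
    p = float(row["p_GG_corr"]) if "p_GG_corr" in aov.columns and not pd.isna(row.get("p_GG_corr")) else float(row["p_unc"])
    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    tukey_df = pg.pairwise_tukey(data=long, dv="value", between="condition")
    tukey = [
        {"a": r["A"], "b": r["B"], "diff": float(r["diff"]), "p": float(r["p_tukey"])}
        for _, r in tukey_df.iterrows()
    ]
    return {"n": n, "underpowered": False, "F": float(row["F"]),
            "df": (df1 * eps, df2 * eps), "p": p, "eps": eps, "tukey": tukey}
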