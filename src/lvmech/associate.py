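"""Association analysis and group comparisons.

Baseline biomechanical factors are related to six-month surrogate
outcomes with Pearson correlation; confidence intervals and two-sided
p-values use the Fisher z-transform (atanh(r) is approximately normal
with SD 1/sqrt(n-3)).  Group comparisons (healthy vs MI marginals) use
the two-sample Student t-test, pooled-variance by default with the Welch
variant available.  Significance is flagged at the conventional 0.05
level; no multiple-testing adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationRow", "pearson_assoc", "association_table",
           "group_compare", "compare_table"]

ALPHA = 0.05


@dataclass
class AssociationRow:
    """One row of an association table: a baseline variable vs an outcome."""

    baseline: str
    outcome: str
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    significant: bool

    def to_dict(self) -> dict:
        return asdict(self)


def pearson_assoc(x, y, baseline: str = "x", outcome: str = "y",
                  alpha: float = ALPHA) -> AssociationRow:
    """Pearson correlation with Fisher-z CI and two-sided p-value.

    Requires n >= 3 finite pairs and nonzero variance in both variables.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zc = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
        p = float(2 * stats.norm.sf(abs(z) / se))
    else:  # |r| = 1 or minimal n: degenerate Fisher interval
        lo, hi, p = r, r, 0.0 if abs(r) == 1.0 else 1.0
    return AssociationRow(baseline=baseline, outcome=outcome, r=r,
                          ci_low=float(lo), ci_high=float(hi), p=p, n=n,
                          significant=bool(p <= alpha))


def association_table(df: pd.DataFrame, baselines, outcomes) -> pd.DataFrame:
    """Pearson associations of every baseline column with every outcome."""
    rows = []
    for out in outcomes:
        for base in baselines:
            rows.append(pearson_assoc(df[base], df[out], base, out).to_dict())
    return pd.DataFrame(rows)


def group_compare(healthy, mi, variable: str = "", welch: bool = False) -> dict:
    """Two-sample t-test between group values plus descriptive statistics.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(healthy, float)
    b = np.asarray(mi, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {"variable": variable,
            "healthy_mean": float(a.mean()), "healthy_sd": float(a.std(ddof=1)),
            "mi_mean": float(b.mean()), "mi_sd": float(b.std(ddof=1)),
            "n_healthy": int(a.size), "n_mi": int(b.size),
            "t": float(t), "p": float(p), "significant": bool(p <= ALPHA)}


def compare_table(df: pd.DataFrame, variables, label_col: str = "label") -> pd.DataFrame:
    """Group-comparison table over ``variables`` for a labelled cohort."""
    h = df[df[label_col] == "healthy"]
    m = df[df[label_col] == "mi"]
    return pd.DataFrame([group_compare(h[v], m[v], v) for v in variables])
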