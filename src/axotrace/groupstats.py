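"""Group-comparison statistics: unpaired t tests and one-way ANOVA + Tukey.

Implementation rides on scipy/statsmodels; the test suite checks both
against textbook sum-of-squares and studentized-range oracles.  Means are
reported +/- SEM.  No multiplicity correction is applied across distinct
transport parameters (each is tested on its own); Tukey's HSD adjusts
only within one ANOVA family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float
    p_value: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    group_means: List[float] = field(default_factory=list)
    group_sems: List[float] = field(default_factory=list)
    note: str = ""

    def to_row(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "note": self.note,
        }


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    return arr


def _sem(arr: np.ndarray) -> float:
    return float(arr.std(ddof=1) / math.sqrt(len(arr)))


def two_group_test(a, b, equal_variance: bool = False,
                   confidence: float = 0.95) -> TestResult:
    """Unpaired two-sided t test (pooled or Welch) with a CI on the difference."""
    a, b = _clean(a), _clean(b)
    name = "Student t (pooled)" if equal_variance else "Welch t"
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        same = a.mean() == b.mean()
        diff = a.mean() - b.mean()
        return TestResult(
            test_name=name,
            statistic=0.0 if same else math.inf,
            df=len(a) + len(b) - 2,
            p_value=1.0 if same else 0.0,
            ci_low=diff, ci_high=diff,
            group_means=[float(a.mean()), float(b.mean())],
            group_sems=[0.0, 0.0],
            note="degenerate: zero variance in both groups",
        )
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    ci = res.confidence_interval(confidence)
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        group_means=[float(a.mean()), float(b.mean())],
        group_sems=[_sem(a), _sem(b)],
    )


def multi_group_test(groups: Sequence, labels: Optional[Sequence[str]] = None):
    """One-way ANOVA with Tukey's HSD post hoc; returns (TestResult, table).

    The table has one row per group pair with the mean difference, the
    Tukey-adjusted p, and the simultaneous 95% confidence bounds.
    """
    if len(groups) < 3:
        raise ValueError("multi_group_test needs >= 3 groups; use two_group_test")
    arrays = [_clean(g) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels must match groups")

    f_stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    anova = TestResult(
        test_name="one-way ANOVA",
        statistic=float(f_stat),
        df=float(n_total - k),
        p_value=float(p),
        group_means=[float(a.mean()) for a in arrays],
        group_sems=[_sem(a) for a in arrays],
        note=f"df_between={k - 1}, df_within={n_total - k}",
    )

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    grp = np.concatenate([[lab] * len(arr) for lab, arr in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, grp, alpha=0.05)
    # build from full-precision attributes (the summary table rounds p)
    import itertools

    pairs = list(itertools.combinations(tukey.groupsunique, 2))
    table = pd.DataFrame({
        "group1": [p[0] for p in pairs],
        "group2": [p[1] for p in pairs],
        "meandiff": np.asarray(tukey.meandiffs, dtype=float),
        "p_adj": np.asarray(tukey.pvalues, dtype=float),
        "ci_low": np.asarray(tukey.confint[:, 0], dtype=float),
        "ci_high": np.asarray(tukey.confint[:, 1], dtype=float),
        "reject": np.asarray(tukey.reject, dtype=bool),
    })
    return anova, table


def comparison_table(results: Sequence[tuple]) -> pd.DataFrame:
    """Assemble (comparison label, TestResult) pairs into one flat table."""
    rows = []
    for label, result in results:
        row = {"comparison": label}
        row.update(result.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
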