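"""Group-comparison statistics for per-neuron metrics.

The tests mirror the ones used for this kind of per-neuron data:
unpaired t-test (Welch by default), Mann–Whitney U (exact for small
samples without ties), Wilcoxon signed-rank against a hypothetical
value of 1 (for ratio/normalized metrics whose null is "no change"),
Kruskal–Wallis, and two-way ANOVA (Type II sums of squares) for
factorial designs.  Computation is delegated to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "compare_groups", "wilcoxon_vs_one", "anova_two_way", "kruskal_wallis"]

TESTS = ("t", "mann_whitney_u", "wilcoxon_signed_rank_vs_1")


def _summary(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
        "median": float(np.median(v)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    group_summaries: list[dict[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"invalid p-value {self.p_value}")


def compare_groups(values_a, values_b, test: str = "t", equal_var: bool = False) -> TestResult:
    """Compare two groups of per-neuron values.

    ``test`` is one of ``"t"`` (Welch by default; ``equal_var=True``
    for the pooled-variance version), ``"mann_whitney_u"`` (exact
    enumeration when min(n) ≤ 8 and there are no ties, normal
    approximation with tie correction otherwise), or
    ``"wilcoxon_signed_rank_vs_1"`` (``values_b`` ignored; tests
    ``values_a`` against the hypothetical value 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float) if values_b is not None else None
    if test == "wilcoxon_signed_rank_vs_1":
        return wilcoxon_vs_one(a)
    if b is None or a.size < 2 or b.size < 2:
        raise ValueError("two-sample tests need >= 2 values per group")
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=equal_var)
    elif test == "mann_whitney_u":
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        if np.ptp(np.concatenate([a, b])) == 0:
            raise ValueError("all values identical: rank test undefined")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(a), _summary(b)],
    )


def wilcoxon_vs_one(values, hypothetical: float = 1.0) -> TestResult:
    """Wilcoxon signed-rank test of a sample against a hypothetical value."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    diffs = v - hypothetical
    if np.all(diffs == 0):
        raise ValueError("all values equal the hypothetical value: test undefined")
    method = "exact" if v.size <= 25 and np.all(diffs != 0) else "approx"
    res = sps.wilcoxon(diffs, alternative="two-sided", method=method)
    return TestResult(
        test="wilcoxon_signed_rank_vs_1",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(v)],
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal–Wallis H-test across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    res = sps.kruskal(*arrays)
    return TestResult(
        test="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=[_summary(g) for g in arrays],
    )


def anova_two_way(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way ANOVA (Type II sums of squares) on a tidy table.

    Returns the statsmodels ANOVA table with F statistics and p-values
    for both main effects (and the interaction when requested).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    op = "*" if interaction else "+"
    model = smf.ols(f"{value} ~ C({factor_a}) {op} C({factor_b})", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)
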