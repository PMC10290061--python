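"""Group comparison of per-subject temporal CAP metrics.

Each CAP's per-subject metric (median duration or occurrence percentage) is
compared between the two genotype groups, with BH-FDR correction across the
K CAPs tested for the same metric. Two tests are available: the pooled
two-sample t-test (df = n1 + n2 - 2) and the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import benjamini_hochberg

TESTS = ("two_sample_t", "rank_sum")


@dataclass
class GroupComparisonResult:
    cap_id: int
    metric: str
    test: str
    statistic: float
    df: Optional[float]
    p_raw: float
    p_adjusted: Optional[float]
    significant_fdr: Optional[bool]
    median_wt: float
    median_het: float
    n_wt: int
    n_het: int
    n_dropped: int = 0


def _one_comparison(values_wt, values_het, test):
    a = np.asarray(values_wt, dtype=float)
    b = np.asarray(values_het, dtype=float)
    dropped = int(np.isnan(a).sum() + np.isnan(b).sum())
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 subjects per group after dropping "
                         "missing values")
    if test == "two_sample_t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    elif test == "rank_sum":
        stat, p = stats.ranksums(a, b)
        df = None
    else:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    return float(stat), df, float(p), float(np.median(a)), \
        float(np.median(b)), a.size, b.size, dropped


def compare_temporal_metric(values_wt, values_het, test: str = "two_sample_t",
                            metric: str = "duration", cap_id: int = 0
                            ) -> GroupComparisonResult:
    """Compare one CAP's metric between groups (raw p, no FDR).

    Subjects with a missing value (the CAP never occurred for them) are
    dropped pairwise; the count of dropped values is recorded.
    """
    stat, df, p, med_a, med_b, n_a, n_b, dropped = _one_comparison(
        values_wt, values_het, test)
    return GroupComparisonResult(
        cap_id=cap_id, metric=metric, test=test, statistic=stat, df=df,
        p_raw=p, p_adjusted=None, significant_fdr=None, median_wt=med_a,
        median_het=med_b, n_wt=n_a, n_het=n_b, n_dropped=dropped)


def compare_all_caps(metrics_df: pd.DataFrame, metric_column: str,
                     test: str = "two_sample_t", q: float = 0.05,
                     groups: Sequence[str] = ("WT", "HET")) -> pd.DataFrame:
    """Run the per-CAP comparison for every CAP and BH-correct across CAPs.

    ``metrics_df`` is the tidy table from
    :func:`capdyn.metrics.subject_cap_metrics`.
    """
    metric_name = metric_column.replace("mean_duration_frames", "duration") \
        .replace("occurrence_pct", "occurrence")
    results = []
    for cap_id, sub in metrics_df.groupby("cap_id"):
        vals = {g: sub.loc[sub["group"] == g, metric_column].to_numpy()
                for g in groups}
        results.append(compare_temporal_metric(
            vals[groups[0]], vals[groups[1]], test=test,
            metric=metric_name, cap_id=int(cap_id)))
    p_raw = np.array([r.p_raw for r in results])
    reject = benjamini_hochberg(p_raw, q=q)
    # BH-adjusted p-values for reporting (monotone step-up)
    order = np.argsort(p_raw)
    m = len(p_raw)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate(
        (p_raw[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    rows = []
    for r, rej, pa in zip(results, reject, adj):
        r.p_adjusted, r.significant_fdr = float(pa), bool(rej)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)
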