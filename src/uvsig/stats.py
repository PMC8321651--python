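"""Group-comparison and survival statistics.

Implements the comparison families used across the study's figures:
Mann-Whitney U for absolute burdens, pairwise t-tests with Holm
adjustment for class frequencies, Kruskal-Wallis followed by pairwise
Mann-Whitney with Benjamini-Hochberg correction ("nonparametric ANOVA"),
one-way ANOVA with Tukey HSD or Fisher LSD post hocs, the Kaplan-Meier
product-limit estimator, and the Gehan-Breslow-Wilcoxon weighted
log-rank test for melanoma-free survival.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

METHODS = ("mann_whitney", "kruskal_bh", "t_holm", "anova_tukey", "anova_lsd")


@dataclass
class GroupTestResult:
    comparison: tuple[str, str]
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class SurvivalRecord:
    subject_id: str
    time: float
    event: bool
    group: str

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"non-positive survival time for {self.subject_id}")


def _exact_mwu(x, y) -> tuple[float, float]:
    n = len(x) + len(y)
    method = "exact" if n <= 20 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    method: str,
    alpha: float = 0.05,
) -> list[GroupTestResult]:
    """Pairwise group comparisons with the family's stated adjustment.

    mann_whitney: pairwise U tests, unadjusted (exact for combined
    n <= 20).  kruskal_bh: Kruskal-Wallis omnibus, then pairwise
    Mann-Whitney with Benjamini-Hochberg FDR adjustment.  t_holm:
    pairwise Welch t-tests with Holm's step-down adjustment.
    anova_tukey: one-way ANOVA with Tukey's HSD post hoc.  anova_lsd:
    one-way ANOVA with Fisher's LSD (unadjusted pairwise t after the
    omnibus F).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    df = pd.DataFrame({"value": values, "group": groups})
    by = {g: sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group")}
    labels = sorted(by)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g, v in by.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
        if method in ("t_holm", "anova_tukey", "anova_lsd") and len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 observations for {method}")

    pairs = list(combinations(labels, 2))
    results: list[GroupTestResult] = []

    if method == "mann_whitney":
        for a, b in pairs:
            u, p = _exact_mwu(by[a], by[b])
            results.append(GroupTestResult((a, b), method, u, p, p))
        return results

    if method == "kruskal_bh":
        raw = []
        stat_pairs = []
        for a, b in pairs:
            u, p = _exact_mwu(by[a], by[b])
            stat_pairs.append(u)
            raw.append(p)
        adj = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
        for (a, b), u, p, q in zip(pairs, stat_pairs, raw, adj):
            results.append(GroupTestResult((a, b), method, u, p, float(q)))
        return results

    if method == "t_holm":
        raw, stat_pairs = [], []
        for a, b in pairs:
            t, p = sps.ttest_ind(by[a], by[b], equal_var=False)
            stat_pairs.append(float(t))
            raw.append(float(p))
        adj = multipletests(raw, alpha=alpha, method="holm")[1]
        for (a, b), t, p, q in zip(pairs, stat_pairs, raw, adj):
            results.append(GroupTestResult((a, b), method, t, p, float(q)))
        return results

    # ANOVA-based families
    f_stat, f_p = sps.f_oneway(*[by[g] for g in labels])
    if method == "anova_tukey":
        tk = sps.tukey_hsd(*[by[g] for g in labels])
        for i, j in combinations(range(len(labels)), 2):
            results.append(
                GroupTestResult(
                    (labels[i], labels[j]),
                    method,
                    float(tk.statistic[i, j]),
                    float(f_p),
                    float(tk.pvalue[i, j]),
                )
            )
        return results

    # Fisher LSD: pooled-variance pairwise t, unadjusted, reported
    # alongside the omnibus F (significance should be read only when the
    # omnibus rejects)
    n_total = sum(len(v) for v in by.values())
    dof = n_total - len(labels)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / dof
    for a, b in pairs:
        va, vb = by[a], by[b]
        se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
        t = (va.mean() - vb.mean()) / se
        p = 2 * sps.t.sf(abs(t), dof)
        results.append(GroupTestResult((a, b), method, float(t), float(p), float(p)))
    return results


def results_to_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.comparison[0],
                "group_b": r.comparison[1],
                "method": r.method,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
            }
            for r in results
        ]
    )


def km_estimate(records: Sequence[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit survival curves, one per group.

    Right-censoring is honored; each curve starts at 1.  Returns a frame
    per group with columns time and survival.
    """
    if not records:
        raise ValueError("no survival records")
    if not any(r.event for r in records):
        pass  # all-censored groups yield flat curves
    out: dict[str, pd.DataFrame] = {}
    df = pd.DataFrame(
        [{"group": r.group, "time": r.time, "event": r.event} for r in records]
    )
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        out[str(g)] = sf
    return out


def gehan_breslow_wilcoxon(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon two-group survival comparison.

    A weighted log-rank test whose weight at each event time is the
    number at risk, emphasising early differences between curves.
    Returns (chi-square statistic with 1 d.f., p-value).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain subjects")
    ta = [r.time for r in group_a]
    tb = [r.time for r in group_b]
    ea = [r.event for r in group_a]
    eb = [r.event for r in group_b]
    res = logrank_test(
        ta, tb, event_observed_A=ea, event_observed_B=eb, weightings="wilcoxon"
    )
    return float(res.test_statistic), float(res.p_value)


def survival_records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Long-format (subject, group, time, event) table to records."""
    return [
        SurvivalRecord(
            subject_id=str(r["subject"]),
            time=float(r["time"]),
            event=bool(r["event"]),
            group=str(r["group"]),
        )
        for r in df.to_dict("records")
    ]
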