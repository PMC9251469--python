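"""Cohort-level MO-vs-IM comparisons, survival analysis, and concordance.

Continuous burden metrics are compared with a Welch t-test or Mann-Whitney U;
gene mutation frequencies with Fisher's exact test on per-sample 2x2 counts;
progression-free survival with Kaplan-Meier curves and the log-rank test.
Concordance quantifies agreement between the molecular (Jaccard-based) and
pathologist calls as percent agreement over the patients with a definite
pathology call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ConcordanceResult",
    "gene_frequency_table",
    "fisher_exact",
    "mann_whitney",
    "student_t",
    "km_logrank",
    "concordance",
]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    groups: Mapping[str, dict]
    test: str
    statistic: float
    p_value: float

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_agree: int

    def __post_init__(self):
        if self.n_agree > self.n_total:
            raise ValueError("n_agree cannot exceed n_total")

    @property
    def percent_agreement(self) -> float:
        return 100.0 * self.n_agree / self.n_total

    @property
    def percent_rounded(self) -> float:
        """Percent agreement rounded to one decimal, as reported."""
        return round(self.percent_agreement, 1)


def gene_frequency_table(
    group_labels: Sequence[str], mutated_flags: Sequence[bool]
) -> np.ndarray:
    """2x2 counts [[IM mutated, IM wild-type], [MO mutated, MO wild-type]].

    Counting is per sample: each lesion contributes one count.
    """
    if len(group_labels) != len(mutated_flags):
        raise ValueError("labels and flags must have equal length")
    table = np.zeros((2, 2), dtype=int)
    rows = {"IM": 0, "MO": 1}
    for label, flag in zip(group_labels, mutated_flags):
        if label not in rows:
            raise ValueError(f"sample with unrecognized group label {label!r}")
        table[rows[label], 0 if flag else 1] += 1
    return table


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)`` with the sample odds ratio (ad)/(bc),
    ``inf`` when bc = 0 and ad > 0.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    (a, b), (c, d) = t
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the pooled sample size is at most 12 and there are
    no ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact_ok = pooled.size <= 12 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def student_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def km_logrank(
    times: Sequence[float], events: Sequence[bool], groups: Sequence[str]
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the log-rank test between groups.

    Returns ``(curves, chi2, p)`` where each curve is a DataFrame with
    columns ``time`` and ``survival`` (the product-limit estimate, a step
    function dropping at each event time).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups, dtype=object)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    labels = pd.unique(groups)
    curves: dict[str, pd.DataFrame] = {}
    for label in labels:
        mask = groups == label
        if not mask.any():
            raise ValueError(f"group {label!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], event_observed=events[mask])
        sf = kmf.survival_function_
        curves[str(label)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if len(labels) < 2:
        return curves, float("nan"), float("nan")
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def concordance(
    molecular: Mapping[str, str], pathology: Mapping[str, str]
) -> ConcordanceResult:
    """Percent agreement between molecular and pathology MO/IM calls.

    Patients labelled "unknown" in either call set are excluded, which also
    makes the measure symmetric in its two arguments.
    """
    shared = sorted(set(molecular) & set(pathology))
    compared = [
        pid
        for pid in shared
        if molecular[pid] != "unknown" and pathology[pid] != "unknown"
    ]
    if not compared:
        raise ValueError("no comparable patients (empty overlap after excluding unknowns)")
    agree = sum(1 for pid in compared if molecular[pid] == pathology[pid])
    return ConcordanceResult(n_total=len(compared), n_agree=agree)
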