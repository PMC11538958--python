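"""Cross-dataset statistics for repertoire analysis.

Covers the descriptive type-level summary (per-type mean frequency and
duration, with global min / max / mean / sd), dataset-exclusivity
labelling of call types, the normality-gated omnibus comparison
(Shapiro–Wilk deciding between one-way ANOVA and Kruskal–Wallis, with
Bonferroni-adjusted pairwise post hoc tests), and Spearman correlations
among the frequency parameters.

Normality is assessed on residuals pooled across groups (values minus
their group mean), which keeps a single gate for the whole comparison;
per-group testing is available behind ``pooled_residuals=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst

DEFAULT_ALPHA = 0.05
#: a dataset needs at least this many exclusive call types to be tested
DEFAULT_MIN_GROUP_N = 2


@dataclass
class StatsConfig:
    alpha: float = DEFAULT_ALPHA
    min_group_n: int = DEFAULT_MIN_GROUP_N

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class TestResult:
    """Outcome of one normality-gated group comparison."""

    test_name: str            # "ANOVA" or "Kruskal-Wallis"
    statistic: float          # F or H
    p_value: float
    groups: list
    decision_path: str        # "normal -> ANOVA" or "non-normal -> Kruskal-Wallis"
    shapiro_w: float
    shapiro_p: float
    posthoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def label_exclusivity(repertoire, min_group_n: int = DEFAULT_MIN_GROUP_N):
    """Label each call type by its sole dataset, or "mixed".

    Returns ``(labels, eligible_datasets)``: ``labels`` maps type label
    to the dataset holding all of its occurrences (or ``"mixed"`` when
    several datasets contribute); ``eligible_datasets`` lists datasets
    with at least ``min_group_n`` exclusive types — datasets below that
    floor are too sparse to enter group comparisons.
    """
    labels = {}
    exclusive_counts: dict = {}
    for t in repertoire.types:
        present = [ds for ds, n in t.per_dataset.items() if n > 0]
        if len(present) == 1:
            labels[t.type_label] = present[0]
            exclusive_counts[present[0]] = exclusive_counts.get(present[0], 0) + 1
        else:
            labels[t.type_label] = "mixed"
    eligible = sorted(ds for ds, n in exclusive_counts.items() if n >= min_group_n)
    return labels, eligible


def summarize_types(type_table: pd.DataFrame) -> dict:
    """Type-level summary in the catalogue's standard layout.

    ``type_table`` carries one row per call type with columns
    ``f_mean_hz`` and ``dur_s`` (type-level means).  Returns the table
    plus global minimum / maximum / mean / standard deviation (n-1
    denominator) per measure; the sd is reported as absent (None) for a
    single type rather than 0.
    """
    summary: dict = {"per_type": type_table.copy(), "global": {}}
    for col, name in (("f_mean_hz", "frequency_hz"), ("dur_s", "duration_s")):
        if type_table.empty:
            summary["global"][name] = {}
            continue
        vals = type_table[col].to_numpy(dtype=float)
        summary["global"][name] = {
            "minimum": float(vals.min()),
            "maximum": float(vals.max()),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        }
    return summary


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def gated_group_test(groups: dict, cfg: StatsConfig | None = None,
                     pooled_residuals: bool = True) -> TestResult:
    """Normality-gated omnibus comparison of one acoustic parameter.

    A Shapiro–Wilk test at level ``alpha`` decides the branch: normal
    data go to one-way ANOVA, non-normal data to Kruskal–Wallis (with
    tie correction).  When the omnibus p-value is at or below ``alpha``,
    all pairwise comparisons are attached (two-sided t-tests on the
    ANOVA branch, Mann–Whitney U on the Kruskal–Wallis branch) with
    Bonferroni-adjusted p-values.
    """
    cfg = cfg or StatsConfig()
    names = sorted(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups to compare")
    if any(a.size < 3 for a in arrays):
        raise ValueError("every group needs at least 3 values")

    if pooled_residuals:
        resid = np.concatenate([a - a.mean() for a in arrays])
        w, p_norm = sst.shapiro(resid)
    else:
        per = [sst.shapiro(a) for a in arrays]
        w = float(np.mean([r.statistic for r in per]))
        p_norm = float(min(r.pvalue for r in per))

    normal = p_norm > cfg.alpha
    if normal:
        stat, p = sst.f_oneway(*arrays)
        name, path = "ANOVA", "normal -> ANOVA"
    else:
        stat, p = sst.kruskal(*arrays)
        name, path = "Kruskal-Wallis", "non-normal -> Kruskal-Wallis"

    posthoc = None
    if p <= cfg.alpha:
        rows = []
        pairs = list(combinations(range(len(names)), 2))
        for i, j in pairs:
            if normal:
                s, praw = sst.ttest_ind(arrays[i], arrays[j])
            else:
                s, praw = sst.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            rows.append({"group_a": names[i], "group_b": names[j],
                         "statistic": float(s), "p_raw": float(praw),
                         "p_bonferroni": _bonferroni(float(praw), len(pairs))})
        posthoc = pd.DataFrame(rows)

    return TestResult(name, float(stat), float(p), names, path,
                      float(w), float(p_norm), posthoc)


def frequency_correlations(type_table: pd.DataFrame) -> dict:
    """Spearman correlations among type-level min / mean / max frequencies.

    Returns ``{(a, b): (rho, p)}`` for the (min,max), (min,mean) and
    (mean,max) pairs; a constant input vector yields ``(None, None)``
    for the affected pairs.
    """
    if len(type_table) < 3:
        raise ValueError("need at least 3 call types for correlations")
    cols = {"min": "f_min_hz", "mean": "f_mean_hz", "max": "f_max_hz"}
    out = {}
    for a, b in (("min", "max"), ("min", "mean"), ("mean", "max")):
        x = type_table[cols[a]].to_numpy(dtype=float)
        y = type_table[cols[b]].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[(a, b)] = (None, None)
            continue
        rho, p = sst.spearmanr(x, y)
        out[(a, b)] = (float(rho), float(p))
    return out
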