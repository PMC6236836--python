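"""Per-feature sensitivity testing across acquisition contrasts.

For each acquisition contrast (magnet strength, flip angle, NEX, platform)
every texture feature is tested for a between-group difference.  Two-level
contrasts use the pooled-variance (Student) two-sample t-test; the
seven-level flip-angle contrast uses one-way ANOVA.  The resulting family of
p-values (one per feature, one family per contrast) is corrected with the
Benjamini-Hochberg step-up false-discovery-rate procedure; the adjusted
values are reported as Q-values and flagged significant at Q < alpha
(default 0.05).

The statistical unit is the slice: group n are slice counts, and
within-dataset correlation between slices is deliberately not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .texture_features import FEATURE_NAMES

__all__ = [
    "ComparisonResult",
    "t_test_two_group",
    "anova_multi_group",
    "benjamini_hochberg",
    "run_contrast",
    "results_to_frame",
]


@dataclass
class ComparisonResult:
    """Outcome of one feature's test for one contrast.

    ``group_stats`` maps each contrast level to (mean, SD, n) over slices.
    ``stat`` is the t statistic for two-level contrasts, the F statistic for
    multi-level ones (``stat_name`` says which).
    """

    feature: str
    group_stats: Dict[Hashable, Tuple[float, float, int]]
    stat: float
    stat_name: str
    p_value: float
    q_value: float = float("nan")
    significant: bool = False


def t_test_two_group(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pooled-variance two-sample t-test, two-tailed.

    Degenerate zero-variance inputs are resolved explicitly: equal means give
    (t=0, p=1); unequal means give an infinite t and p=0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("groups must be finite")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sx2 == 0 and sy2 == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means", RuntimeWarning)
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def anova_multi_group(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way ANOVA across groups (flip-angle contrast).

    With two groups this reduces to the pooled t-test (F = t^2).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must be finite")
    if all(g.var(ddof=1) == 0 for g in arrays):
        means = [g.mean() for g in arrays]
        if np.ptp(means) == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means", RuntimeWarning)
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on exactly-equal groups
        f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # all groups identical element-wise
        return 0.0, 1.0
    return float(f), float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at 1;
    ties keep their original order (stable sort).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_contrast(
    feature_table: pd.DataFrame,
    contrast: str,
    feature_names: Optional[List[str]] = None,
    alpha: float = 0.05,
) -> List[ComparisonResult]:
    """Test every feature for a between-group difference along one contrast.

    ``feature_table`` holds one row per slice with feature columns plus a
    column named after the contrast variable.  Two observed levels are
    compared with the pooled t-test, three or more (flip angle) with one-way
    ANOVA.  One Benjamini-Hochberg family spans the tested features of this
    contrast.
    """
    if contrast not in feature_table.columns:
        raise ValueError(f"feature table has no {contrast!r} column")
    names = feature_names if feature_names is not None else [
        n for n in FEATURE_NAMES if n in feature_table.columns
    ]
    if not names:
        raise ValueError("no feature columns to test")
    levels = sorted(feature_table[contrast].unique())
    if len(levels) < 2:
        raise ValueError(f"contrast {contrast!r} has fewer than 2 levels")

    results: List[ComparisonResult] = []
    for name in names:
        groups = [
            feature_table.loc[feature_table[contrast] == lv, name].to_numpy()
            for lv in levels
        ]
        gstats = {
            lv: (float(g.mean()), float(g.std(ddof=1)), int(g.size))
            for lv, g in zip(levels, groups)
        }
        if len(levels) == 2:
            stat, p = t_test_two_group(groups[0], groups[1])
            stat_name = "t"
        else:
            stat, p = anova_multi_group(groups)
            stat_name = "F"
        results.append(
            ComparisonResult(
                feature=name, group_stats=gstats, stat=stat,
                stat_name=stat_name, p_value=p,
            )
        )
    q = benjamini_hochberg([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv < alpha)
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a table mirroring the report layout."""
    rows = []
    for r in results:
        row: Dict[str, object] = {"feature": r.feature}
        for lv, (mean, sd, n) in r.group_stats.items():
            row[f"mean[{lv}]"] = mean
            row[f"sd[{lv}]"] = sd
            row[f"n[{lv}]"] = n
        row[r.stat_name] = r.stat
        row["p_value"] = r.p_value
        row["q_value"] = r.q_value
        row["significant"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows)
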