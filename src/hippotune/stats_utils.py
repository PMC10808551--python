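"""Statistical hygiene: outlier removal, normality gating, test selection.

The conventions applied before every group comparison:

* missing (NaN) values are dropped first and excluded from reported n;
* extreme outliers — values more than 3 interquartile ranges outside
  [Q1, Q3] of their empirical distribution — are removed in a single pass
  (fences from the original sample);
* each group is tested for normality with a Kolmogorov-Smirnov test at
  alpha = 0.05 against a Gaussian with the sample mean and SD (note this
  plug-in reference makes the test anti-conservative in the Lilliefors
  sense; it mirrors the stated protocol);
* normally distributed data get parametric tests (Student's t / ANOVA),
  otherwise rank-based tests (signed-rank if paired, rank-sum for two
  groups, Kruskal-Wallis for more).

Aggregation to session or animal level averages cells within each group so
downstream tests can use sessions/animals as the statistical unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatReport",
    "remove_extreme_outliers",
    "choose_and_run_test",
    "aggregate",
]


@dataclass
class StatReport:
    variable: str
    n_before: int
    n_after: int
    normality_p: tuple[float, ...]
    test_used: str
    statistic: float
    p_value: float
    aggregation_level: str = "cell"


def remove_extreme_outliers(values: np.ndarray, k: float = 3.0) -> tuple[np.ndarray, int]:
    """Drop values outside [Q1 - k*IQR, Q3 + k*IQR]; single pass.

    NaNs are dropped first (and not counted as removed outliers). With
    IQR = 0 the fences collapse onto the quartiles and nothing beyond
    exactly-equal values is kept out, so an all-equal sample is unchanged.
    Returns (filtered values, number of outliers removed).
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite values")
    if finite.size < 4:
        return finite, 0
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    keep = (finite >= q1 - k * iqr) & (finite <= q3 + k * iqr)
    return finite[keep], int((~keep).sum())


def _ks_normal_p(x: np.ndarray) -> float:
    """KS test p-value against N(mean(x), sd(x))."""
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(x, "norm", args=(np.mean(x), sd)).pvalue)


def choose_and_run_test(
    groups: list[np.ndarray],
    paired: bool = False,
    alpha: float = 0.05,
    variable: str = "",
    outlier_k: float = 3.0,
    aggregation_level: str = "cell",
) -> StatReport:
    """Outlier-clean the groups, gate on normality, and run the right test.

    Two normal groups get a t test (paired or independent), more get a
    one-way ANOVA; non-normal data get Wilcoxon signed-rank (paired),
    rank-sum (two groups) or Kruskal-Wallis (more). Identical groups give
    p near 1 on either route.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_before = sum(int(np.isfinite(np.asarray(g, dtype=float)).sum()) for g in groups)
    if paired:
        # pairing forbids per-group outlier removal that would break alignment
        cleaned = [np.asarray(g, dtype=float) for g in groups]
        lengths = {len(g) for g in cleaned}
        if len(lengths) != 1:
            raise ValueError("paired groups must have equal length")
        ok = np.all([np.isfinite(g) for g in cleaned], axis=0)
        cleaned = [g[ok] for g in cleaned]
    else:
        cleaned = [remove_extreme_outliers(g, k=outlier_k)[0] for g in groups]
    for g in cleaned:
        if len(g) < 3:
            raise ValueError("each group needs >= 3 values after cleaning")
    n_after = sum(len(g) for g in cleaned)
    norm_p = tuple(_ks_normal_p(g) for g in cleaned)
    normal = all(p > alpha for p in norm_p)

    if normal:
        if paired:
            if np.all(cleaned[0] == cleaned[1]):
                name, s, p = "paired t-test", np.nan, 1.0
            else:
                name, (s, p) = "paired t-test", stats.ttest_rel(cleaned[0], cleaned[1])
        elif len(cleaned) == 2:
            name, (s, p) = "t-test", stats.ttest_ind(cleaned[0], cleaned[1])
        else:
            name, (s, p) = "one-way ANOVA", stats.f_oneway(*cleaned)
    else:
        if paired:
            diffs = cleaned[0] - cleaned[1]
            if np.all(diffs == 0):
                name, s, p = "wilcoxon signed-rank", np.nan, 1.0
            else:
                name, (s, p) = "wilcoxon signed-rank", stats.wilcoxon(
                    cleaned[0], cleaned[1])
        elif len(cleaned) == 2:
            name, (s, p) = "rank-sum", stats.ranksums(cleaned[0], cleaned[1])
        else:
            name, (s, p) = "kruskal-wallis", stats.kruskal(*cleaned)
    return StatReport(
        variable=variable, n_before=n_before, n_after=n_after,
        normality_p=norm_p, test_used=name, statistic=float(s),
        p_value=float(p), aggregation_level=aggregation_level,
    )


def aggregate(
    values: pd.DataFrame,
    level: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """Average a per-cell table up to session or animal level.

    ``values`` needs columns linking cells to sessions/animals
    (``session_id`` and/or ``animal_id``). ``level`` is one of
    {"cell", "session", "animal"}; "cell" is the identity. Group sizes are
    reported in an ``n`` column.
    """
    if level == "cell":
        out = values.copy()
        out["n"] = 1
        return out
    key = {"session": "session_id", "animal": "animal_id"}.get(level)
    if key is None:
        raise ValueError("level must be one of cell/session/animal")
    if key not in values.columns:
        raise ValueError(f"missing linkage column '{key}'")
    if values[key].isna().any():
        raise ValueError(f"missing values in linkage column '{key}'")
    grouped = values.groupby(key)[value_col].agg(["mean", "size"]).reset_index()
    return grouped.rename(columns={"mean": value_col, "size": "n"})
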