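"""Group comparisons for reporting.

Thin routing over standard tests: Shapiro-Wilk normality checks choose
between the parametric (t) and non-parametric (Mann-Whitney / Wilcoxon)
branch for unpaired or paired designs.  All novel computation lives
upstream; this exists so result tables can carry the usual statistics
column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    normal: bool
    flagged: bool = False
    note: str = ""


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sstats.shapiro(x).pvalue > alpha


def compare_two(
    a,
    b,
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> TestResult:
    """Compare two samples, routing on normality.

    Normally distributed data (both groups passing Shapiro-Wilk) get a t
    test (paired or independent); otherwise Wilcoxon signed-rank (paired)
    or Mann-Whitney U (unpaired).  Degenerate groups (n < 2) are flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return TestResult("none", float("nan"), float("nan"), a.size, b.size,
                          False, flagged=True, note="degenerate group (n < 2)")
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal group sizes")
    normal = _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha)
    if paired:
        if np.allclose(a, b):
            return TestResult("wilcoxon", 0.0, 1.0, a.size, b.size, normal,
                              note="identical paired samples")
        if normal:
            res = sstats.ttest_rel(a, b)
            name = "paired_t"
        else:
            res = sstats.wilcoxon(a, b)
            name = "wilcoxon"
    else:
        if normal:
            res = sstats.ttest_ind(a, b)
            name = "t"
        else:
            res = sstats.mannwhitneyu(a, b, alternative="two-sided")
            name = "mann_whitney"
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      a.size, b.size, normal)


def compare_groups(
    table: pd.DataFrame,
    value: str,
    group: str,
    paired_on: str | None = None,
    measure: str = "",
) -> pd.DataFrame:
    """Pairwise group comparisons of one measure in a long-form table.

    ``paired_on`` names a column identifying matched observations (e.g. the
    tunnel id across timepoints); when given, groups are aligned on it and
    compared with the paired branch.
    """
    rows = []
    levels = list(pd.unique(table[group]))
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            ga = table[table[group] == levels[i]]
            gb = table[table[group] == levels[j]]
            if paired_on is not None:
                merged = pd.merge(ga, gb, on=paired_on, suffixes=("_a", "_b"))
                res = compare_two(merged[f"{value}_a"], merged[f"{value}_b"], paired=True)
            else:
                res = compare_two(ga[value].dropna(), gb[value].dropna())
            rows.append(dict(
                measure=measure or value, group_a=levels[i], group_b=levels[j],
                test=res.test_name, statistic=res.statistic, p_value=res.p_value,
                n_a=res.n_a, n_b=res.n_b, normal=res.normal,
                flagged=res.flagged, note=res.note,
            ))
    return pd.DataFrame(rows)
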