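"""Subgroup-vs-subgroup cytokine comparison tables.

Per analyte and contrast (e.g. High vs Low): medians and interquartile
ranges in pM, the ratio of (unrounded) medians, a Welch two-sample t-test on
log10 values, and Benjamini-Hochberg adjustment across the analyte family
within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import MolarMatrix, log10_view
from .subgrouping import SubgroupAssignment


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns (t, Welch-Satterthwaite df, p).  When both groups have zero
    variance and equal means the test is vacuous and p = 1 by convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonRow:
    """One analyte's summary for one subgroup contrast."""

    analyte_id: str
    contrast: tuple[str, str]  # (numerator label, denominator label)
    medians_pM: dict[str, float]
    iqrs_pM: dict[str, tuple[float, float]]
    ratio_of_medians: float
    t_stat: float
    welch_df: float
    p_raw: float
    q_bh: float


def subgroup_summary_table(
    matrix: MolarMatrix,
    assignment: SubgroupAssignment,
    contrasts: list[tuple[str, str]],
    pool_contrasts: bool = False,
) -> pd.DataFrame:
    """Comparison table over all analytes for the given label contrasts.

    Each contrast is (numerator, denominator), e.g. ("High", "Low").  The BH
    family is the analyte set within one contrast unless ``pool_contrasts``.
    Rows are sorted by ratio descending within each contrast.
    """
    logm = log10_view(matrix)
    rows = []
    for num_label, den_label in contrasts:
        for label in (num_label, den_label):
            if len(assignment.members(label)) == 0:
                raise ValueError(f"empty subgroup in contrast: {label}")
        num_ids = assignment.members(num_label)
        den_ids = assignment.members(den_label)
        if len(num_ids) < 2 or len(den_ids) < 2:
            raise ValueError("each contrasted subgroup needs >= 2 patients")
        for analyte in matrix.analyte_ids:
            x = matrix.values.loc[num_ids, analyte].to_numpy(float)
            y = matrix.values.loc[den_ids, analyte].to_numpy(float)
            t, df, p = welch_t(np.log10(x), np.log10(y))
            rows.append(
                {
                    "contrast": f"{num_label}:{den_label}",
                    "analyte_id": analyte,
                    f"median_{num_label}": np.median(x),
                    f"q1_{num_label}": np.percentile(x, 25),
                    f"q3_{num_label}": np.percentile(x, 75),
                    f"median_{den_label}": np.median(y),
                    f"q1_{den_label}": np.percentile(y, 25),
                    f"q3_{den_label}": np.percentile(y, 75),
                    "ratio_of_medians": float(np.median(x) / np.median(y)),
                    "t_stat": t,
                    "welch_df": df,
                    "p_raw": p,
                }
            )
    table = pd.DataFrame(rows)
    if pool_contrasts:
        table["q_bh"] = bh_adjust(table["p_raw"].to_numpy())
    else:
        table["q_bh"] = np.nan
        for _, idx in table.groupby("contrast").groups.items():
            table.loc[idx, "q_bh"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
    table = (
        table.sort_values(["contrast", "ratio_of_medians"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return table
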