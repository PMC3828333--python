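"""Kaplan-Meier curves, G-rho rank tests, and subgroup transition analysis.

The G-rho family weights each event time by S(t-)^rho, the left-continuous
pooled Kaplan-Meier estimate; rho = 0 reduces to the standard log-rank test,
rho = 1 to a Peto-Prentice-style test emphasising early events.  The
transition analysis cross-tabulates each patient's baseline subgroup against
their 24-hour subgroup and compares every cell's survival with the rest of
its baseline (and 24-hour) subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2

from .panel_io import ClinicalTable
from .subgrouping import SubgroupAssignment


@dataclass
class SurvivalTestResult:
    chisq: float
    df: int
    p: float
    rho: float = 0.0


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate under right-censoring.

    Returns a step function as a frame with columns ``time`` and
    ``survival``; the curve starts at (0, 1).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def g_rho_test(times, events, group_labels, rho: float = 0.0) -> SurvivalTestResult:
    """k-sample G-rho rank test; rho = 0 is the standard log-rank test."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(group_labels)
    if not (times.size == events.size == groups.size):
        raise ValueError("times, events and group_labels must align")
    levels, gidx = np.unique(groups, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("need at least 2 groups")

    order = np.argsort(times, kind="stable")
    times, events, gidx = times[order], events[order], gidx[order]
    n_total = times.size

    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    surv_left = 1.0  # pooled KM just before the current event time
    for t in event_times:
        at_risk = times >= t
        n_i = int(at_risk.sum())
        dying = (times == t) & (events == 1)
        d_i = int(dying.sum())
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_ij = np.bincount(gidx[dying], minlength=k).astype(float)
        w = surv_left**rho
        observed += w * d_ij
        expected += w * d_i * n_ij / n_i
        if n_i > 1:
            frac = n_ij / n_i
            hyper_var = d_i * (n_i - d_i) / (n_i - 1)
            cov += w**2 * hyper_var * (np.diag(frac) - np.outer(frac, frac))
        surv_left *= 1.0 - d_i / n_i

    u = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    if not np.any(v):
        chisq = 0.0
    else:
        chisq = float(u @ np.linalg.pinv(v) @ u)
        chisq = max(chisq, 0.0)
    p = float(chi2.sf(chisq, k - 1))
    return SurvivalTestResult(chisq=chisq, df=k - 1, p=p, rho=rho)


@dataclass
class TransitionTable:
    """Per (baseline subgroup, 24h subgroup) cell counts and survival tests."""

    table: pd.DataFrame  # columns: from_label, to_label, n, deaths_day90, ...


def transition_analysis(
    baseline: SubgroupAssignment,
    late: SubgroupAssignment,
    clinical: ClinicalTable,
    rho: float = 0.0,
) -> TransitionTable:
    """Cross-tabulate subgroup transitions with per-cell mortality and tests.

    For each (from, to) cell the patients' survival is compared (G-rho test)
    against the other members of the same baseline subgroup, and against the
    other members of the same 24-hour subgroup.  Cells whose complement
    within a reference subgroup is empty get p = NaN.
    """
    ids = list(baseline.patient_ids)
    if set(ids) != set(late.patient_ids):
        raise ValueError("assignments must cover the same patients")
    clin = clinical.table.loc[ids]
    b_labels = baseline.labels.loc[ids]
    l_labels = late.labels.loc[ids]

    rows = []
    for from_label in baseline.label_order:
        for to_label in late.label_order:
            cell_ids = [
                p for p in ids if b_labels[p] == from_label and l_labels[p] == to_label
            ]
            n = len(cell_ids)
            deaths = int(clin.loc[cell_ids, "death_day90"].sum()) if n else 0
            row = {
                "from_label": from_label,
                "to_label": to_label,
                "n": n,
                "deaths_day90": deaths,
                "mortality_pct": 100.0 * deaths / n if n else np.nan,
                "p_vs_baseline_subgroup": np.nan,
                "p_vs_24h_subgroup": np.nan,
            }
            if n > 0:
                for key, ref_labels, ref_label in (
                    ("p_vs_baseline_subgroup", b_labels, from_label),
                    ("p_vs_24h_subgroup", l_labels, to_label),
                ):
                    ref_ids = [
                        p
                        for p in ids
                        if ref_labels[p] == ref_label and p not in set(cell_ids)
                    ]
                    if ref_ids:
                        sub = cell_ids + ref_ids
                        membership = ["cell"] * len(cell_ids) + ["rest"] * len(ref_ids)
                        res = g_rho_test(
                            clin.loc[sub, "survival_time"],
                            clin.loc[sub, "event"],
                            membership,
                            rho=rho,
                        )
                        row[key] = res.p
            rows.append(row)
    table = pd.DataFrame(rows)
    if table["n"].sum() != len(ids):
        raise AssertionError("transition cells must partition the cohort")
    return TransitionTable(table)
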