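"""Subgroup mortality at uniform illness severity (APACHE-matched sampling).

To ask whether subgroup membership predicts death beyond illness severity,
patients are repeatedly subsampled so that every subgroup contributes the
identical multiset of APACHE II scores: for each score present in all
subgroups, the minimum per-subgroup count at that score is drawn without
replacement from each subgroup.  Day-28 mortality is then compared between
each subgroup and the reference (High) subgroup by Fisher's exact test, and
the per-iteration odds ratios and p-values are summarised by their medians
and empirical 2.5-97.5 percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .panel_io import ClinicalTable
from .subgrouping import SubgroupAssignment

logger = logging.getLogger(__name__)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (p, odds_ratio).  The p-value sums, over all tables with the
    observed margins, the probabilities no larger than the observed table's.
    The odds ratio is the sample cross-product a*d/(b*c), with a
    Haldane-Anscombe 0.5 added to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    t = np.rint(t).astype(int)
    p = float(_scipy_fisher(t, alternative="two-sided")[1])
    a, b, c, d = t.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return p, float(odds_ratio)


@dataclass
class MatchedIteration:
    sampled_ids: dict[str, list[str]]  # per subgroup label
    tables: dict[str, np.ndarray]  # comparison label -> 2x2 (dead/alive)
    odds_ratios: dict[str, float]
    p_values: dict[str, float]
    apache_multiset: list[int]


def _matched_sample(
    rng: np.random.Generator,
    labels: pd.Series,
    apache: pd.Series,
    label_order: list[str],
) -> dict[str, list[str]]:
    """Identical-APACHE-multiset samples, one per subgroup."""
    common_scores = None
    per_label_scores: dict[str, pd.Series] = {}
    for lab in label_order:
        ids = labels.index[labels == lab]
        scores = apache.loc[ids]
        per_label_scores[lab] = scores
        counts = set(scores.unique())
        common_scores = counts if common_scores is None else (common_scores & counts)
    if not common_scores:
        raise ValueError("no APACHE score present in all subgroups")
    sampled: dict[str, list[str]] = {lab: [] for lab in label_order}
    for s in sorted(common_scores):
        n_s = min(int((per_label_scores[lab] == s).sum()) for lab in label_order)
        for lab in label_order:
            pool = list(per_label_scores[lab].index[per_label_scores[lab] == s])
            take = rng.choice(len(pool), size=n_s, replace=False)
            sampled[lab].extend(pool[i] for i in sorted(take))
    return sampled


def severity_matched_iteration(
    assignment: SubgroupAssignment,
    clinical: ClinicalTable,
    reference_label: str = "High",
    seed: int = 0,
    death_column: str = "death_day28",
) -> MatchedIteration:
    """One APACHE-matched resampling iteration with Fisher comparisons.

    Comparisons: each non-reference subgroup vs the reference, plus the
    pooled non-reference subgroups (e.g. "Low+Medium") when there are
    several.  2x2 tables are (comparison, reference) x (dead, alive).
    """
    if reference_label not in assignment.label_order:
        raise ValueError(f"unknown reference label {reference_label!r}")
    if assignment.k < 2:
        raise ValueError("need at least 2 subgroups")
    rng = np.random.default_rng(seed)
    ids = assignment.patient_ids
    apache = clinical.table.loc[ids, "apache2"].astype(int)
    deaths = clinical.table.loc[ids, death_column].astype(int)
    sampled = _matched_sample(rng, assignment.labels, apache, assignment.label_order)

    multiset = sorted(apache.loc[sampled[reference_label]].tolist())
    for lab in assignment.label_order:
        if sorted(apache.loc[sampled[lab]].tolist()) != multiset:
            raise AssertionError("APACHE multisets differ across matched samples")

    others = [lab for lab in assignment.label_order if lab != reference_label]
    comparisons = {lab: [lab] for lab in others}
    if len(others) > 1:
        comparisons["+".join(others)] = others

    ref_ids = sampled[reference_label]
    ref_dead = int(deaths.loc[ref_ids].sum())
    tables, ors, ps = {}, {}, {}
    for name, labs in comparisons.items():
        cmp_ids = [p for lab in labs for p in sampled[lab]]
        cmp_dead = int(deaths.loc[cmp_ids].sum())
        table = np.array(
            [
                [cmp_dead, len(cmp_ids) - cmp_dead],
                [ref_dead, len(ref_ids) - ref_dead],
            ]
        )
        p, odds = fisher_exact_2x2(table)
        tables[name], ors[name], ps[name] = table, odds, p
    return MatchedIteration(sampled, tables, ors, ps, multiset)


@dataclass
class MatchedSummary:
    reference_label: str
    n_iterations: int
    n_matched_per_subgroup: int
    apache_min: int
    apache_median: float
    apache_max: int
    summary: pd.DataFrame  # per comparison: median OR/p with percentile CIs
    iterations: pd.DataFrame  # per iteration x comparison: odds_ratio, p
    n_redrawn: int = 0


def matched_mortality_summary(
    assignment: SubgroupAssignment,
    clinical: ClinicalTable,
    reference_label: str = "High",
    n_iter: int = 100,
    seed: int = 0,
    death_column: str = "death_day28",
) -> MatchedSummary:
    """Repeat APACHE-matched sampling ``n_iter`` times and summarise.

    Degenerate iterations (a zero margin in some 2x2 table, e.g. no deaths
    at all among the matched patients) are redrawn with a fresh substream
    and counted.  Summaries are medians and empirical 2.5-97.5 percentile
    intervals over iterations, computed on sorted values so the result does
    not depend on iteration order.
    """
    master = np.random.default_rng(seed)
    records = []
    kept = 0
    redrawn = 0
    last: MatchedIteration | None = None
    attempts_cap = 20 * n_iter
    attempts = 0
    while kept < n_iter and attempts < attempts_cap:
        attempts += 1
        child_seed = int(master.integers(2**31))
        try:
            it = severity_matched_iteration(
                assignment, clinical, reference_label, child_seed, death_column
            )
        except ValueError:
            redrawn += 1
            continue
        last = it
        kept += 1
        for name in it.odds_ratios:
            records.append(
                {
                    "iteration": kept,
                    "comparison": name,
                    "odds_ratio": it.odds_ratios[name],
                    "p": it.p_values[name],
                }
            )
    if kept < n_iter:
        raise RuntimeError("too many degenerate matched-sampling iterations")
    if redrawn:
        logger.info("matched sampling: %d degenerate iterations redrawn", redrawn)

    iterations = pd.DataFrame(records)
    rows = []
    for name, sub in iterations.groupby("comparison", sort=False):
        ors = np.sort(sub["odds_ratio"].to_numpy())
        ps = np.sort(sub["p"].to_numpy())
        rows.append(
            {
                "comparison": name,
                "or_median": float(np.median(ors)),
                "or_ci_low": float(np.percentile(ors, 2.5)),
                "or_ci_high": float(np.percentile(ors, 97.5)),
                "p_median": float(np.median(ps)),
                "p_ci_low": float(np.percentile(ps, 2.5)),
                "p_ci_high": float(np.percentile(ps, 97.5)),
            }
        )
    assert last is not None
    multiset = last.apache_multiset
    return MatchedSummary(
        reference_label=reference_label,
        n_iterations=n_iter,
        n_matched_per_subgroup=len(multiset),
        apache_min=int(min(multiset)),
        apache_median=float(np.median(multiset)),
        apache_max=int(max(multiset)),
        summary=pd.DataFrame(rows),
        iterations=iterations,
        n_redrawn=redrawn,
    )
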