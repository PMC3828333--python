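"""Over-representation (enrichment) analysis by the hypergeometric tail.

Tests whether a categorical clinical feature is over-represented in a
patient subgroup — or a pathway membership in an analyte cluster — relative
to the whole population, using the upper tail of the hypergeometric
distribution, with Benjamini-Hochberg adjustment over the full
feature x cluster family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .group_stats import bh_adjust
from .panel_io import ClinicalTable
from .subgrouping import SubgroupAssignment

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    feature_id: str
    cluster_label: str
    k: int  # feature-positive inside the cluster
    n: int  # cluster size
    K: int  # feature-positive in the population
    N: int  # population size
    p_hyper: float
    q_bh: float
    fold_enrichment: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k must lie in [0, min(n, K)]: k={k}, K={K}, n={n}, N={N}")
    # survival function is P(X > k-1) = P(X >= k); stable in log space inside scipy
    return float(hypergeom.sf(k - 1, N, K, n))


def _binary_features(clinical: ClinicalTable) -> pd.DataFrame:
    """Feature indicator matrix; multi-level categoricals become one-vs-rest."""
    cols = {}
    table = clinical.table
    for feat in clinical.feature_columns:
        col = table[feat]
        values = col.dropna().unique()
        if set(values) <= {0, 1, True, False}:
            cols[feat] = col.astype(int)
        else:
            for level in sorted(map(str, values)):
                cols[f"{feat}={level}"] = (col.astype(str) == level).astype(int)
    cols["death_day28"] = table["death_day28"].astype(int)
    cols["death_day90"] = table["death_day90"].astype(int)
    return pd.DataFrame(cols, index=table.index)


def _enrich(
    indicator: pd.DataFrame, groups: pd.Series, labels: list[str]
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail test per feature x cluster, BH over all."""
    N = len(groups)
    results = []
    for feat in indicator.columns:
        K = int(indicator[feat].sum())
        if K == 0:
            logger.info("feature %s has no positives overall; skipped", feat)
            continue
        for label in labels:
            members = groups.index[groups == label]
            n = len(members)
            k = int(indicator.loc[members, feat].sum())
            p = hypergeom_upper_tail(k, K, n, N)
            fold = (k / n) / (K / N) if n > 0 else 0.0
            results.append(
                EnrichmentResult(feat, str(label), k, n, K, N, p, np.nan, fold)
            )
    if results:
        q = bh_adjust([r.p_hyper for r in results])
        for r, qv in zip(results, q):
            r.q_bh = float(qv)
    return results


def feature_enrichment(
    clinical: ClinicalTable, assignment: SubgroupAssignment
) -> list[EnrichmentResult]:
    """Enrichment of clinical features (incl. day-28/90 death) in subgroups."""
    ids = assignment.patient_ids
    indicator = _binary_features(clinical.subset(ids))
    return _enrich(indicator, assignment.labels, assignment.label_order)


def membership_enrichment(
    analyte_clusters: pd.Series, membership_map: dict[str, set[str]]
) -> list[EnrichmentResult]:
    """Enrichment of pathway memberships in analyte clusters.

    ``membership_map`` maps analyte_id to the set of pathway ids it belongs
    to (a user-supplied occupancy table; no database access).  Both raw p
    and BH q are reported.
    """
    if not membership_map:
        raise ValueError("membership map is empty")
    analytes = list(analyte_clusters.index)
    pathways = sorted({p for s in membership_map.values() for p in s})
    indicator = pd.DataFrame(
        {pw: [int(pw in membership_map.get(a, set())) for a in analytes] for pw in pathways},
        index=analytes,
    )
    cluster_labels = [str(c) for c in sorted(analyte_clusters.unique())]
    groups = analyte_clusters.astype(str)
    return _enrich(indicator, groups, cluster_labels)


def results_frame(results: list[EnrichmentResult], fdr: float = 0.05) -> pd.DataFrame:
    """Tabulate results, flagging significance at the given FDR."""
    df = pd.DataFrame([r.__dict__ for r in results])
    if not df.empty:
        df["significant"] = df["q_bh"] < fdr
        df = df.sort_values(["q_bh", "p_hyper"]).reset_index(drop=True)
    return df


def read_membership_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (analyte_id, pathway_id) -> membership map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("membership file needs columns analyte_id, pathway_id")
    out: dict[str, set[str]] = {}
    for a, p in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(a, set()).add(p)
    return out
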