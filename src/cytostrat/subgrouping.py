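"""Hierarchical clustering of patients and analytes, with ordered labels.

Patients are clustered on per-analyte z-scored log10 pM values (so that
high-abundance analytes do not dominate the distance); the dendrogram is cut
at a user-chosen k and clusters are relabelled Low < (Medium) < High by the
cluster-wise median of each patient's median standardized level, so the
labels reflect overall cytokine burden.  Analytes are clustered on the
transposed standardized matrix, conventionally with correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("complete", "average", "ward")

ORDERED_LABELS = {
    1: ["All"],
    2: ["Low", "High"],
    3: ["Low", "Medium", "High"],
}


@dataclass
class SubgroupAssignment:
    """Patient→cluster map with ordered Low/(Medium)/High labels.

    ``clusters`` maps patient_id to a raw cluster index from the dendrogram
    cut; ``labels`` maps patient_id to the ordered label; ``linkage_record``
    is the scipy merge table (n-1 x 4) for downstream tree/heatmap tooling.
    """

    clusters: pd.Series  # patient_id -> int
    labels: pd.Series  # patient_id -> str
    k: int
    linkage_record: np.ndarray
    label_order: list[str]  # ascending overall level

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clusters.index)

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.label_order, fill_value=0)

    @classmethod
    def from_labels(cls, labels: pd.Series, label_order: list[str]) -> "SubgroupAssignment":
        """Build an assignment from known labels (no dendrogram)."""
        order_index = {lab: i for i, lab in enumerate(label_order)}
        clusters = labels.map(order_index)
        if clusters.isna().any():
            raise ValueError("labels outside label_order")
        return cls(
            clusters=clusters.astype(int),
            labels=labels.astype(str),
            k=len(label_order),
            linkage_record=np.empty((0, 4)),
            label_order=list(label_order),
        )


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-score (per analyte over patients)."""
    sd = matrix.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
    return (matrix - matrix.mean(axis=0)) / sd


def _agglomerate(data: np.ndarray, distance: str, method: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if method == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    n = data.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of observations n={n}")
    if n == 1:
        return np.empty((0, 4)), np.zeros(1, dtype=int)
    dist = pdist(data, metric=distance)
    z = linkage(dist, method=method)
    memberships = cut_tree(z, n_clusters=k).ravel()
    return z, memberships


def cluster_rows(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "ward",
    k: int = 3,
    scale: bool = True,
) -> SubgroupAssignment:
    """Agglomeratively cluster patients (rows of log10 pM) into k subgroups.

    The dendrogram cut is deterministic given the input row order; labels
    are then ordered by overall level via :func:`order_subgroup_labels`.
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix contains missing values")
    work = standardize(matrix) if scale else matrix
    z, memberships = _agglomerate(work.to_numpy(float), distance, linkage_method, k)
    clusters = pd.Series(memberships, index=matrix.index, name="cluster")
    assignment = SubgroupAssignment(
        clusters=clusters,
        labels=clusters.astype(str),  # placeholder until ordered
        k=k,
        linkage_record=z,
        label_order=[],
    )
    return order_subgroup_labels(matrix, assignment, scale=scale)


def order_subgroup_labels(
    matrix: pd.DataFrame, assignment: SubgroupAssignment, scale: bool = True
) -> SubgroupAssignment:
    """Relabel clusters Low < (Medium) < High by overall cytokine level.

    The ordering statistic is the cluster-wise median of each patient's
    median z-scored log10 value.  Exact ties break by cluster size
    descending, then by lowest cluster index.
    """
    if not set(assignment.clusters.index) == set(matrix.index):
        raise ValueError("assignment must cover exactly the matrix patients")
    work = standardize(matrix) if scale else matrix
    per_patient = work.median(axis=1)
    k = assignment.k
    stats = []
    for ci in range(k):
        members = assignment.clusters.index[assignment.clusters == ci]
        if len(members) == 0:
            raise ValueError(f"cluster index {ci} is empty")
        stats.append(
            (float(per_patient.loc[members].median()), -len(members), ci)
        )
    order = sorted(range(k), key=lambda ci: stats[ci])
    names = ORDERED_LABELS.get(k, [f"G{i + 1}" for i in range(k)])
    label_of_cluster = {ci: names[rank] for rank, ci in enumerate(order)}
    labels = assignment.clusters.map(label_of_cluster)
    return SubgroupAssignment(
        clusters=assignment.clusters.copy(),
        labels=labels,
        k=k,
        linkage_record=assignment.linkage_record,
        label_order=list(names),
    )


def cluster_analytes(
    matrix: pd.DataFrame,
    distance: str = "correlation",
    linkage_method: str = "complete",
    k: int = 4,
) -> pd.Series:
    """Cluster analytes by their variation across patients.

    Operates on the transposed per-analyte standardized matrix; returns
    analyte_id -> cluster index (0..k-1).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("matrix contains missing values")
    work = standardize(matrix).T  # analytes x patients
    _, memberships = _agglomerate(work.to_numpy(float), distance, linkage_method, k)
    return pd.Series(memberships, index=work.index, name="analyte_cluster")


def silhouette_report(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage_method: str = "complete",
    k_range: range = range(2, 7),
    scale: bool = True,
) -> pd.Series:
    """Mean silhouette width per candidate k (an aid; never auto-selects)."""
    from sklearn.metrics import silhouette_score

    work = (standardize(matrix) if scale else matrix).to_numpy(float)
    out = {}
    for k in k_range:
        if k >= work.shape[0]:
            break
        _, memberships = _agglomerate(work, distance, linkage_method, k)
        out[k] = float(silhouette_score(work, memberships, metric=distance))
    return pd.Series(out, name="mean_silhouette")
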