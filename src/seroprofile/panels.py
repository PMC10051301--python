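"""Combined-panel analyses: count classifier ROC and binary clustering.

The count classifier labels a sample positive when its load over a marker
panel (number of positive calls) reaches a cutoff k; sweeping k yields a
discrete ROC curve whose trapezoid AUC equals the probability that a
random case outranks a random control (ties at half credit).

Binary autoantibody profiles are clustered agglomeratively with
complete linkage on simple-matching (Hamming proportion) distances —
simple matching rather than Jaccard so that all-negative profiles remain
comparable.  Clusters are renumbered by decreasing within-cluster
autoantibody prevalence, so the least-reactive cluster always carries the
highest label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import (
    CLINICAL_ANTIBODIES,
    CLINICAL_FLAGS,
    BinaryReactivityMatrix,
    SampleRecord,
    ValidationError,
    logger,
    pct_half_up,
)

__all__ = [
    "PanelRocResult",
    "ClusterResult",
    "count_classifier_roc",
    "cluster_samples",
    "cluster_feature_summary",
    "cluster_membership_pct",
    "export_heatmap",
]

DISTANCES = ("matching", "jaccard")
LINKAGES = ("complete", "average", "ward")


@dataclass
class PanelRocResult:
    """ROC of the count classifier over a marker panel."""

    panel: list[str]
    table: pd.DataFrame  # columns: k, tpr, fpr, pct_cases_positive, pct_controls_negative
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError(f"AUC out of range: {self.auc}")


@dataclass
class ClusterResult:
    """Hierarchical clustering of binary profiles."""

    assignment: pd.Series  # sample_id -> 1..k
    linkage: np.ndarray
    leaf_order: list[str]
    k: int
    distance: str = "matching"
    method: str = "complete"
    silhouette: float | None = None
    prevalence_by_cluster: pd.DataFrame | None = None


def count_classifier_roc(
    calls: BinaryReactivityMatrix | pd.DataFrame,
    labels: pd.Series,
    k_max: int | None = None,
    positive_label: str = "case",
) -> PanelRocResult:
    """ROC curve of the "load >= k" classifier for k = 0..k_max+1.

    ``calls`` is the binary matrix restricted to the marker panel.  For
    each cutoff k the sample is classified positive when its panel load is
    at least k; the table reports TPR/FPR plus the half-up-rounded
    percentage of cases classified positive and of controls classified
    negative.  The AUC is the trapezoid area over the step curve anchored
    at (0,0) and (1,1); with ``k_max`` at least the maximum observed load
    (the default) it equals the Mann-Whitney probability of correct
    ordering with half-credit ties.
    """
    df = calls.calls if isinstance(calls, BinaryReactivityMatrix) else calls
    if df.shape[1] == 0:
        raise ValidationError("empty marker panel")
    labels = labels.reindex(df.index)
    load = df.sum(axis=1).astype(int)
    case = labels == positive_label
    n_cases, n_controls = int(case.sum()), int((~case & labels.notna()).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValidationError("both label groups must be non-empty")
    control = ~case & labels.notna()
    if k_max is None:
        k_max = int(load.max())

    rows = []
    for k in range(0, k_max + 2):
        positive = load >= k
        tp = int((positive & case).sum())
        fp = int((positive & control).sum())
        tpr = tp / n_cases
        fpr = fp / n_controls
        rows.append(
            {
                "k": k,
                "tpr": tpr,
                "fpr": fpr,
                "pct_cases_positive": pct_half_up(tp, n_cases),
                "pct_controls_negative": pct_half_up(n_controls - fp, n_controls),
            }
        )
    table = pd.DataFrame(rows)

    pts = sorted(
        set(zip(table["fpr"], table["tpr"])) | {(0.0, 0.0), (1.0, 1.0)}
    )
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(ys, xs))
    logger.info(
        "count classifier over %d markers, %d cases / %d controls: AUC=%.3f",
        df.shape[1], n_cases, n_controls, auc,
    )
    return PanelRocResult(panel=list(df.columns), table=table, auc=auc)


def _binary_distances(mat: np.ndarray, distance: str) -> np.ndarray:
    if distance == "matching":
        return pdist(mat, metric="hamming")
    if distance == "jaccard":
        return pdist(mat, metric="jaccard")
    raise ValueError(f"unknown distance {distance!r}")


def cluster_samples(
    calls: BinaryReactivityMatrix | pd.DataFrame,
    k: int = 4,
    distance: str = "matching",
    method: str = "complete",
) -> ClusterResult:
    """Cut a complete-linkage tree over binary profiles into k clusters.

    Clusters are deterministically renumbered by decreasing mean
    within-cluster prevalence, so cluster k is always the least reactive
    (ties broken by the original dendrogram label).  A silhouette score on
    the same distances is reported as a diagnostic only; it never chooses
    k.
    """
    df = calls.calls if isinstance(calls, BinaryReactivityMatrix) else calls
    if df.shape[0] < k:
        raise ValidationError(f"need at least k={k} samples, got {df.shape[0]}")
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}")
    # canonicalize row order so tied distances break identically for any
    # input permutation of the same samples
    original_index = df.index
    df = df.sort_index(kind="mergesort")
    mat = df.to_numpy(dtype=float)
    if method == "ward":
        dist = pdist(mat, metric="euclidean")
        link = hierarchy.linkage(dist, method="ward")
    else:
        dist = _binary_distances(mat, distance)
        link = hierarchy.linkage(dist, method=method)
    raw_labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    leaf_order = [df.index[i] for i in hierarchy.leaves_list(link)]

    # renumber by decreasing within-cluster prevalence
    prevalence = {
        lab: float(mat[raw_labels == lab].mean()) for lab in np.unique(raw_labels)
    }
    ordered = sorted(prevalence, key=lambda lab: (-prevalence[lab], lab))
    relabel = {old: new + 1 for new, old in enumerate(ordered)}
    assignment = pd.Series(
        [relabel[lab] for lab in raw_labels], index=df.index, name="cluster"
    ).reindex(original_index)

    silhouette = _silhouette(dist, raw_labels) if len(np.unique(raw_labels)) > 1 else None
    prev_table = (
        df.groupby(assignment).mean().sort_index()
    )
    logger.info(
        "clustering %d samples into %d clusters (%s linkage, %s distance)",
        df.shape[0], k, method, distance,
    )
    return ClusterResult(
        assignment=assignment,
        linkage=link,
        leaf_order=leaf_order,
        k=k,
        distance=distance,
        method=method,
        silhouette=silhouette,
        prevalence_by_cluster=prev_table,
    )


def _silhouette(condensed: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over samples, from a condensed distance matrix."""
    from scipy.spatial.distance import squareform

    d = squareform(condensed)
    n = len(labels)
    scores = []
    for i in range(n):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            scores.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(
            d[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        denom = max(a, b)
        scores.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(scores))


def cluster_feature_summary(
    result: ClusterResult, metadata: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Per-cluster prevalence of clinical features and antibody statuses.

    For each cluster and feature: percentage positive among members with a
    non-missing status (rounded half-up); NaN when no member has the
    status assessed.
    """
    meta = {r.sample_id: r for r in metadata}
    missing = [s for s in result.assignment.index if s not in meta]
    if missing:
        raise ValidationError(f"clustered sample(s) absent from metadata: {missing}")
    rows = []
    for cluster in sorted(result.assignment.unique()):
        members = [meta[s] for s in result.assignment.index[result.assignment == cluster]]
        row: dict = {"cluster": cluster, "n": len(members)}
        for name in CLINICAL_FLAGS:
            vals = [m.flag(name) for m in members]
            known = [v for v in vals if v is not None]
            row[name] = pct_half_up(sum(known), len(known)) if known else np.nan
        for name in CLINICAL_ANTIBODIES:
            vals = [m.antibody(name) for m in members]
            known = [v for v in vals if v is not None]
            row[name] = pct_half_up(sum(known), len(known)) if known else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def cluster_membership_pct(
    result: ClusterResult,
    feature_samples: Iterable[str],
    clusters: Sequence[int],
) -> int:
    """Percentage of feature-positive samples falling in the given clusters.

    E.g. "what share of the high-skin-score patients sit in clusters 1 or
    2".  Samples not present in the clustering are ignored.
    """
    feature_samples = [s for s in feature_samples if s in result.assignment.index]
    if not feature_samples:
        raise ValidationError("no feature-positive samples in the clustering")
    inside = sum(
        1 for s in feature_samples if int(result.assignment[s]) in set(clusters)
    )
    return pct_half_up(inside, len(feature_samples))


def export_heatmap(
    calls: BinaryReactivityMatrix | pd.DataFrame,
    result: ClusterResult,
    image_path: str | None = None,
    tsv_path: str | None = None,
) -> pd.DataFrame:
    """Binary heatmap with rows in dendrogram order.

    Returns the reordered DataFrame; optionally writes it as TSV (the
    bit-exact twin of the figure) and renders a purple-on-white matrix
    image.
    """
    df = calls.calls if isinstance(calls, BinaryReactivityMatrix) else calls
    ordered = df.loc[result.leaf_order]
    if tsv_path is not None:
        ordered.to_csv(tsv_path, sep="\t")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * ordered.shape[1]), max(4, 0.12 * ordered.shape[0]))
        )
        ax.imshow(
            ordered.to_numpy(),
            aspect="auto",
            cmap=ListedColormap(["white", "#6a3d9a"]),
            interpolation="nearest",
        )
        ax.set_xticks(range(ordered.shape[1]))
        ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(ordered.shape[0]))
        ax.set_yticklabels(ordered.index, fontsize=5)
        ax.set_xlabel("target")
        ax.set_ylabel("sample (dendrogram order)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return ordered
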