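"""Unsupervised tumor/normal classification of ROI feature tables.

Each feature is Z-scored across all ROIs in the analysis, ROIs are
agglomeratively clustered (Euclidean distance, Ward linkage by default,
with other linkages available) and the tree is cut at two clusters; the
clusters are then oriented as
cancer vs normal either by their mean intensity (cancer tissue shows the
higher mean uptake) or by known sample placement. Confusion counts against
ground truth give false-positive and false-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .features import FEATURE_NAMES

VALID_LABELS = ("cancer", "normal")


@dataclass
class ZScoreResult:
    """Column-standardized feature table plus the features that were constant."""

    table: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    constant_features: list[str]


@dataclass
class ClusterResult:
    """Two-group partition of ROIs with dendrogram bookkeeping.

    Cluster ids are in {1, 2}; id 1 is the cluster containing the
    lowest-index ROI (deterministic tie-break).
    """

    labels: np.ndarray
    roi_linkage: np.ndarray
    feature_linkage: np.ndarray | None
    feature_order: list[str]
    linkage_method: str


def zscore_table(
    table: pd.DataFrame, feature_columns: list[str] | None = None
) -> ZScoreResult:
    """Z-score each feature across all ROIs using the population (n) SD.

    Constant features map to all-zero columns and are reported in
    ``constant_features`` rather than producing NaNs.
    """
    feature_columns = list(feature_columns or [c for c in FEATURE_NAMES if c in table.columns])
    if len(table) < 2:
        raise ValueError("Z-scoring needs at least 2 ROIs")
    x = table[feature_columns].astype(float)
    if not np.isfinite(x.to_numpy()).all():
        raise ValueError("feature table contains non-finite values")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    constant = [c for c in feature_columns if sds[c] == 0]
    safe_sds = sds.replace(0, 1.0)
    z = (x - means) / safe_sds
    z[constant] = 0.0
    return ZScoreResult(table=z, means=means, sds=sds, constant_features=constant)


def cluster_rois(
    ztable: pd.DataFrame, linkage_method: str = "ward"
) -> ClusterResult:
    """Cut the agglomerative Euclidean ROI tree at two clusters.

    Ward linkage by default: with two clouds of unequal within-class
    spread (heterogeneous tumor vs uniform normal tissue) average linkage
    tends to split off a handful of extreme ROIs instead of the two tissue
    groups, while Ward's variance criterion recovers them; any scipy
    linkage method can be passed instead. The feature (row) dendrogram is
    retained for heatmap ordering. With at least two distinct feature
    vectors both clusters are nonempty.
    """
    x = ztable.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("Z-score table contains non-finite values")
    if x.shape[0] < 2:
        raise ValueError("clustering needs at least 2 ROIs")
    roi_linkage = hierarchy.linkage(x, method=linkage_method, metric="euclidean")
    labels = hierarchy.fcluster(roi_linkage, t=2, criterion="maxclust")
    # cluster containing the lowest ROI index gets id 1
    if labels.max() == 2 and labels[0] == 2:
        labels = 3 - labels
    feature_linkage = None
    feature_order = list(ztable.columns)
    if x.shape[1] >= 2:
        col_dist = pdist(x.T, metric="euclidean")
        feature_linkage = hierarchy.linkage(col_dist, method=linkage_method)
        order = hierarchy.leaves_list(feature_linkage)
        feature_order = [ztable.columns[i] for i in order]
    return ClusterResult(
        labels=np.asarray(labels),
        roi_linkage=roi_linkage,
        feature_linkage=feature_linkage,
        feature_order=feature_order,
        linkage_method=linkage_method,
    )


def orient_clusters(
    result: ClusterResult,
    table: pd.DataFrame,
    rule: str = "intensity",
    cancer_sample: str | None = None,
) -> np.ndarray:
    """Map the two anonymous clusters to {cancer, normal} labels per ROI.

    ``rule="intensity"`` labels the cluster with the higher mean
    ``intensity_mean`` as cancer (tumor tissue shows higher tracer uptake);
    ``rule="placement"`` labels the cluster dominated by ROIs from
    ``cancer_sample`` (requires a ``sample`` column), mirroring a-priori
    knowledge of where the cancer slice was placed.
    """
    labels = result.labels
    ids = np.unique(labels)
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")
    if rule == "intensity":
        if "intensity_mean" not in table.columns:
            raise ValueError("intensity rule needs an 'intensity_mean' column")
        means = {cid: table.loc[labels == cid, "intensity_mean"].mean() for cid in ids}
        if means[ids[0]] == means[ids[1]]:
            raise ValueError(
                "clusters have exactly equal mean intensity; orientation is ambiguous — "
                "use the placement rule or choose labels explicitly"
            )
        cancer_id = max(ids, key=lambda cid: means[cid])
    elif rule == "placement":
        if cancer_sample is None or "sample" not in table.columns:
            raise ValueError("placement rule needs cancer_sample and a 'sample' column")
        frac = {
            cid: float((table.loc[labels == cid, "sample"] == cancer_sample).mean())
            for cid in ids
        }
        if frac[ids[0]] == frac[ids[1]]:
            raise ValueError("placement rule is ambiguous for these clusters")
        cancer_id = max(ids, key=lambda cid: frac[cid])
    else:
        raise ValueError(f"unknown orientation rule {rule!r}")
    return np.where(labels == cancer_id, "cancer", "normal")


@dataclass
class ConfusionCounts:
    """Confusion counts with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def false_negative_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "false_positive_rate": self.false_positive_rate,
            "false_negative_rate": self.false_negative_rate,
            "false_positive_rate_pct": round(100 * self.false_positive_rate),
            "false_negative_rate_pct": round(100 * self.false_negative_rate),
            "accuracy": self.accuracy,
        }


def confusion_metrics(predicted, truth) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of predicted vs true {cancer, normal} labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth label lists differ in length")
    for name, arr in (("predicted", predicted), ("truth", truth)):
        bad = set(arr.tolist()) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown {name} labels: {sorted(bad)}")
    return ConfusionCounts(
        tp=int(((predicted == "cancer") & (truth == "cancer")).sum()),
        fp=int(((predicted == "cancer") & (truth == "normal")).sum()),
        tn=int(((predicted == "normal") & (truth == "normal")).sum()),
        fn=int(((predicted == "normal") & (truth == "cancer")).sum()),
    )


def plot_cluster_heatmap(
    zresult: ZScoreResult, cluster: ClusterResult, path, roi_labels=None
) -> None:
    """Save a clustered features-by-ROIs Z-score heatmap (rows = features)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = zresult.table
    roi_order = hierarchy.leaves_list(cluster.roi_linkage)
    data = z.iloc[roi_order][cluster.feature_order].to_numpy().T
    fig, ax = plt.subplots(figsize=(max(6, data.shape[1] * 0.06), 6))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_yticks(range(len(cluster.feature_order)))
    ax.set_yticklabels(cluster.feature_order, fontsize=6)
    ax.set_xlabel("ROIs (dendrogram order)")
    fig.colorbar(im, ax=ax, label="Z-score")
    if roi_labels is not None:
        ordered = np.asarray(roi_labels)[roi_order]
        colors = np.where(ordered == "cancer", 1.0, 0.0)[None, :]
        ax.imshow(
            colors,
            aspect="auto",
            cmap="coolwarm",
            extent=(-0.5, data.shape[1] - 0.5, data.shape[0] + 1.0, data.shape[0] + 0.2),
        )
        ax.set_ylim(data.shape[0] + 1.2, -0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
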