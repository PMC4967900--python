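"""End-to-end workflow: simulate -> extract -> classify -> report.

Ties the phantom generator, ROI geometry, texture features, clustering and
TNR/SNR metrics into reproducible, config-driven runs. The default
two-tissue workflow places one 13 x 6 grid of 20 x 20 px ROIs on each
tissue slice (78 ROIs per sample, 156 total) and classifies them without
using ground truth; the truth mask only enters when confusion rates are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ClusterResult,
    ConfusionCounts,
    ZScoreResult,
    cluster_rois,
    confusion_metrics,
    orient_clusters,
    zscore_table,
)
from .features import FEATURE_NAMES, FeatureConfig, feature_vector
from .io import Image
from .metrics import (
    SNRResult,
    combined_feature_tnr,
    estimate_snr,
    intensity_tnr,
    select_independent_features,
)
from .phantom import (
    DEFAULT_CANCER_RECT,
    DEFAULT_NORMAL_RECT,
    PhantomSpec,
    PointSourceSpec,
    generate_point_source_frame,
    generate_two_tissue_scene,
)
from .roi import ROIGrid, extract_roi, make_roi_grid

ID_COLUMNS = ("sample", "grid_row", "grid_col", "row0", "col0")


def default_two_tissue_grids() -> dict[str, ROIGrid]:
    """One 13 x 6 grid of 20 x 20 px ROIs per tissue slice (78 ROIs each)."""
    return {
        "normal": ROIGrid(
            origin=DEFAULT_NORMAL_RECT[::2], grid_shape=(13, 6), sample="normal"
        ),
        "cancer": ROIGrid(
            origin=DEFAULT_CANCER_RECT[::2], grid_shape=(13, 6), sample="cancer"
        ),
    }


def extract_feature_table(
    image: Image | np.ndarray,
    grids: dict[str, ROIGrid],
    config: FeatureConfig | None = None,
    truth_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Feature table over all grids: one row per ROI, id columns + features.

    With a truth mask, each ROI also gets a ``truth`` label by majority
    vote over its pixels (codes 0/1/2 = background/normal/cancer).
    """
    config = config or FeatureConfig()
    rows = []
    for sample, grid in grids.items():
        make_roi_grid(
            image,
            origin=grid.origin,
            roi_shape=grid.roi_shape,
            grid_shape=grid.grid_shape,
            stride=grid.stride,
        )  # bounds validation
        for roi in grid.rois():
            window = extract_roi(image, roi)
            record = {
                "sample": sample,
                "grid_row": roi.grid_index[0],
                "grid_col": roi.grid_index[1],
                "row0": roi.row0,
                "col0": roi.col0,
            }
            record.update(feature_vector(window, config))
            if truth_mask is not None:
                codes = truth_mask[roi.window].ravel()
                majority = np.bincount(codes, minlength=3).argmax()
                record["truth"] = {0: "background", 1: "normal", 2: "cancer"}[int(majority)]
            rows.append(record)
    return pd.DataFrame(rows)


@dataclass
class ClassificationRun:
    """Outputs of one unsupervised cluster-then-orient pass."""

    table: pd.DataFrame
    zscores: ZScoreResult
    clusters: ClusterResult
    predicted: np.ndarray
    confusion: ConfusionCounts | None = None


def classify_feature_table(
    table: pd.DataFrame,
    linkage_method: str = "ward",
    orientation_rule: str = "intensity",
    cancer_sample: str | None = None,
    truth_column: str | None = None,
) -> ClassificationRun:
    """Z-score, cluster at 2, orient, and (if truth present) count confusions."""
    z = zscore_table(table)
    clusters = cluster_rois(z.table, linkage_method=linkage_method)
    predicted = orient_clusters(
        clusters, table, rule=orientation_rule, cancer_sample=cancer_sample
    )
    confusion = None
    if truth_column is None and "truth" in table.columns:
        truth_column = "truth"
    if truth_column is not None and truth_column in table.columns:
        truth = table[truth_column].to_numpy()
        keep = np.isin(truth, ("cancer", "normal"))
        confusion = confusion_metrics(predicted[keep], truth[keep])
    return ClassificationRun(
        table=table, zscores=z, clusters=clusters, predicted=predicted, confusion=confusion
    )


def run_two_tissue_pipeline(
    seed: int,
    rim_on: bool = False,
    feature_config: FeatureConfig | None = None,
    linkage_method: str = "ward",
    **scene_kwargs,
) -> ClassificationRun:
    """Simulate a two-slice scene and classify its ROIs fully unsupervised.

    Ground truth per ROI is the sample the ROI grid was placed on; it is
    used only for the confusion counts, never for clustering or
    orientation.
    """
    image, _labels = generate_two_tissue_scene(seed=seed, rim_on=rim_on, **scene_kwargs)
    table = extract_feature_table(image, default_two_tissue_grids(), feature_config)
    table["truth"] = table["sample"]
    return classify_feature_table(table, linkage_method=linkage_method)


def simulate_point_source_snr(
    acquisition_time: float,
    seed: int,
    total_rate: float = 23_000.0,
    psf_sigma: float = 3.0,
    read_noise_sd: float = 3.0,
    offset: float = 100.0,
    center: tuple[float, float] = (150.0, 200.0),
) -> SNRResult:
    """Simulate a dried-spot frame and fit its SNR.

    Default rates put the spot amplitude around 200 counts at 1 s so the
    estimator operates in the shot-noise regime (sigma_bg**2 << A) where
    SNR grows like sqrt(t).
    """
    spec = PhantomSpec(
        regions=(),
        acquisition_time=acquisition_time,
        gain=1.0,
        read_noise_sd=read_noise_sd,
        offset=offset,
        seed=seed,
    )
    source = PointSourceSpec(center=center, total_rate=total_rate, psf_sigma=psf_sigma)
    image = generate_point_source_frame(source, spec)
    r0, c0 = int(center[0]), int(center[1])
    half = max(6, int(6 * psf_sigma))
    signal_window = (r0 - half, r0 + half, c0 - half, c0 + half)
    background_window = (10, 80, 10, 80)
    return estimate_snr(image.pixels, signal_window, background_window)


def tnr_report(
    table: pd.DataFrame,
    labels,
    independence_threshold: float = 0.95,
    combiner: str = "sum",
) -> dict:
    """Intensity TNR plus the combined multi-feature TNR, as a JSON-able dict."""
    labels = np.asarray(labels)
    cancer_mean = float(table.loc[labels == "cancer", "intensity_mean"].mean())
    normal_mean = float(table.loc[labels == "normal", "intensity_mean"].mean())
    feature_columns = [c for c in FEATURE_NAMES if c in table.columns]
    independent = select_independent_features(
        table, feature_columns, threshold=independence_threshold
    )
    tnr = combined_feature_tnr(table, labels, independent, combiner=combiner)
    return {
        "intensity_tnr": cancer_mean / normal_mean,
        "cancer_mean_intensity": cancer_mean,
        "normal_mean_intensity": normal_mean,
        "independent_features": independent,
        "n_independent_features": len(independent),
        "per_feature_tnr": tnr.per_feature,
        "combiner": combiner,
        "combined_tnr": tnr.combined,
        "combined_tnr_by_combiner": tnr.combined_by,
        "tnr_improvement_factor": tnr.combined / (cancer_mean / normal_mean),
    }
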