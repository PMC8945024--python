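"""Descriptive summaries: z-scored matrices, PCA projections, median
trajectory tables and ranked top-feature tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


def zscore_matrix(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-standardize a features x samples matrix (mean 0, SD 1, ddof=1).

    Constant rows become all-zero and are flagged in the returned boolean
    Series.
    """
    if values.shape[1] < 2:
        raise ValueError("z-scoring requires at least two samples")
    v = values.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant] = 1.0
    z = (v - mean) / sd
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=values.index, columns=values.columns),
        pd.Series(constant, index=values.index, name="constant"),
    )


def pca_project(
    values: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto principal components of a features x samples
    matrix.

    Samples are the observations; features are centered.  Components are
    ordered by decreasing explained variance, and each component's sign is
    fixed so its largest-magnitude feature loading is positive.  Returns
    ``(coordinates, explained_variance_ratio)``.
    """
    n_samples = values.shape[1]
    if n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    max_comp = min(n_samples, values.shape[0])
    if n_components is None:
        n_components = min(max_comp, n_samples - 1)
    elif n_components > max_comp:
        log.warning("pca_project: clipping n_components to %d", max_comp)
        n_components = max_comp
    X = values.to_numpy(dtype=float).T  # samples x features
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for k in range(pca.components_.shape[0]):
        j = int(np.abs(pca.components_[k]).argmax())
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            coords[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def trajectory_summary(
    values: pd.DataFrame,
    design,
    feature_ids,
    assay: str,
    arms_timepoints: list[tuple[str, int]],
    reference: tuple[str, int] = ("0h", 0),
    mode: str = "expression",
    order: str = "median_of_means",
) -> pd.DataFrame:
    """Per-arm trajectory relative to the time-zero control.

    Expression mode reports ``log2(median / reference median)`` where the
    median is taken over features of the per-feature group mean
    (``order='median_of_means'``) or the group mean of per-feature medians
    (``order='mean_of_medians'``).  Methylation mode reports the change in
    the median value versus the reference group.
    """
    feats = values.loc[list(feature_ids)]

    def group_stat(arm: str, tp: int) -> float:
        samples = design.arm_samples(assay, arm, tp)
        sub = feats[samples]
        if order == "median_of_means":
            return float(sub.mean(axis=1).median())
        if order == "mean_of_medians":
            return float(sub.median(axis=1).mean())
        raise ValueError(f"unknown order {order!r}")

    ref = group_stat(*reference)
    rows = []
    for arm, tp in arms_timepoints:
        g = group_stat(arm, tp)
        if mode == "expression":
            denom = ref
            if denom <= 0:
                log.info("trajectory_summary: zero reference median; applying pseudocount")
                denom = ref + 0.1
                g = g + 0.1
            rows.append((arm, tp, g, np.log2(g / denom)))
        elif mode == "methylation":
            rows.append((arm, tp, g, g - ref))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    col = "log2_fc_of_median" if mode == "expression" else "delta_median"
    return pd.DataFrame(rows, columns=["arm", "timepoint_h", "group_stat", col])


def rank_top_features(
    stats_df: pd.DataFrame,
    key: str = "effect",
    n: int = 10,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-n features by |key|, descending; ties break by feature_id.

    When an annotation table (e.g. nearest-gene assignments) is given, its
    columns are joined onto the result.
    """
    df = stats_df.copy()
    df["_abs_key"] = df[key].abs()
    df["_fid"] = df.index.astype(str)
    df = df.sort_values(["_abs_key", "_fid"], ascending=[False, True], kind="mergesort")
    df = df.drop(columns=["_abs_key", "_fid"]).head(n)
    if annotation is not None:
        df = df.join(annotation, how="left")
    return df
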