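"""Unsupervised validation views of a DE protein panel.

These views never see the group labels during fitting: hierarchical
clustering and PCA operate on the (DE-restricted) normalized matrix alone,
and the labels enter only afterwards, to summarize how well the unsupervised
structure recovers the case/control split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.decomposition import PCA

from serodiff.cohort import validate_design
from serodiff.matrix import IntensityMatrix

__all__ = [
    "ClusterResult",
    "PcaResult",
    "cluster_heatmap",
    "pca_scores",
    "volcano",
    "top_protein_boxes",
]

#: Display-standardization clip bound (z units), the usual heatmap range.
CLIP = 3.0


@dataclass(frozen=True)
class ClusterResult:
    display: pd.DataFrame  # per-protein z-scores clipped to [-CLIP, CLIP]
    protein_linkage: np.ndarray
    sample_linkage: np.ndarray
    sample_leaf_order: list[str]
    sample_clusters: pd.Series  # 2-cluster cut labels (1/2), indexed by sample
    confusion: pd.DataFrame  # cluster x group counts
    n_misassigned: int


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    separation: float  # between-centroid dist / mean within-group dist


def _impute_row_means(values: np.ndarray) -> np.ndarray:
    """Fill missing entries with the protein's mean (z = 0 after
    standardization); distances and PCA need complete data."""
    out = values.copy()
    row_means = np.nanmean(out, axis=1)
    idx = np.where(np.isnan(out))
    out[idx] = np.take(row_means, idx[0])
    return out


def cluster_heatmap(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of proteins and samples on z-standardized
    values, with the sample tree cut at 2 clusters and compared against the
    group labels.

    Per-protein standardization uses the sample SD (ddof=1); standardized
    values are clipped to +/-3 for display.  Constant protein rows are
    excluded with a warning.  The misassignment count is the minimum over
    the two possible cluster-to-group matchings.
    """
    validate_design(design)
    if matrix.n_proteins < 2:
        raise ValueError("need at least 2 proteins to cluster")
    values = matrix.data.to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(values, axis=1, ddof=1)
    constant = ~(sd > 0)
    if constant.any():
        dropped = list(matrix.data.index[constant])
        warnings.warn(f"excluding constant protein rows: {dropped}")
        values = values[~constant]
        index = matrix.data.index[~constant]
        sd = sd[~constant]
    else:
        index = matrix.data.index
    if values.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant proteins")

    z = (values - np.nanmean(values, axis=1)[:, None]) / sd[:, None]
    z_full = _impute_row_means(z)
    display = pd.DataFrame(
        np.clip(z, -CLIP, CLIP), index=index, columns=matrix.data.columns
    )

    protein_link = linkage(z_full, method=method, metric=metric)
    sample_link = linkage(z_full.T, method=method, metric=metric)
    leaf_order = [matrix.samples[i] for i in leaves_list(sample_link)]
    cut = fcluster(sample_link, t=2, criterion="maxclust")
    clusters = pd.Series(cut, index=matrix.samples, name="cluster")

    group = design.set_index("sample_id")["group"].reindex(matrix.samples)
    confusion = pd.crosstab(clusters, group)
    confusion = confusion.reindex(columns=["CCA", "BBTD"], fill_value=0)
    # best of the two cluster<->group matchings
    if len(confusion) == 2:
        a = confusion.iloc[0, 1] + confusion.iloc[1, 0]
        b = confusion.iloc[0, 0] + confusion.iloc[1, 1]
        n_mis = int(min(a, b))
    else:  # degenerate single cluster
        n_mis = int(confusion.iloc[0].min())
    return ClusterResult(
        display=display,
        protein_linkage=protein_link,
        sample_linkage=sample_link,
        sample_leaf_order=leaf_order,
        sample_clusters=clusters,
        confusion=confusion,
        n_misassigned=n_mis,
    )


def pca_scores(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    n_components: int = 3,
    scale: bool = False,
) -> PcaResult:
    """PCA of samples (observations) over proteins (features).

    Features are centered; unit-variance scaling is off by default since the
    pipeline's inputs are already quantile-normalized.  The separation
    summary is the distance between the two group centroids in component
    space divided by the mean distance of samples to their own group
    centroid (> 1 indicates groups further apart than their spread).
    """
    validate_design(design)
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples for PCA")
    X = _impute_row_means(matrix.data.to_numpy(dtype=float)).T  # samples x proteins
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    scores_df = pd.DataFrame(
        scores,
        index=matrix.samples,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )

    group = design.set_index("sample_id")["group"].reindex(matrix.samples)
    cent = {g: scores[group.to_numpy() == g].mean(axis=0) for g in ("CCA", "BBTD")}
    between = float(np.linalg.norm(cent["CCA"] - cent["BBTD"]))
    within = float(
        np.mean(
            [
                np.linalg.norm(scores[i] - cent[group.iloc[i]])
                for i in range(len(group))
            ]
        )
    )
    separation = between / within if within > 0 else np.inf
    return PcaResult(
        scores=scores_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        separation=separation,
    )


def volcano(detable: pd.DataFrame, cutoff: float = 0.01) -> pd.DataFrame:
    """Volcano coordinates: log2 fold change (CCA - BBTD) against
    -log10 of the worst-case (max) per-fold p, one point per quantifiable
    protein.  The DE flag uses the strict inequality p < cutoff."""
    q = detable[detable["quantifiable"]]
    fc = q["mean_cca"] - q["mean_bbtd"]
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(q["max_fold_p"])
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "neg_log10_p": neg_log_p,
            "is_de": q["max_fold_p"] < cutoff,
        },
        index=q.index,
    )


def top_protein_boxes(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    proteins: list[str] | None = None,
    n_top: int = 5,
    detable: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Five-number summaries (min, Q1, median, Q3, max) per group for a
    protein panel, on the normalized log2 scale.

    When ``proteins`` is None, the ``n_top`` DE proteins with the largest
    absolute fold change are taken from ``detable``.  Quartiles use linear
    interpolation.  Unknown protein ids raise ``KeyError`` listing them.
    """
    validate_design(design)
    if proteins is None:
        if detable is None:
            raise ValueError("either proteins or detable must be given")
        de = detable[detable["is_de"]]
        fc = (de["mean_cca"] - de["mean_bbtd"]).abs()
        proteins = fc.sort_values(ascending=False, kind="mergesort").index[:n_top].tolist()
    missing = [p for p in proteins if p not in matrix.data.index]
    if missing:
        raise KeyError(f"unknown protein ids: {missing}")

    group = design.set_index("sample_id")["group"].reindex(matrix.samples)
    rows = []
    for p in proteins:
        vals = matrix.data.loc[p]
        for g in ("CCA", "BBTD"):
            x = vals[group.to_numpy() == g].dropna().to_numpy()
            if x.size == 0:
                rows.append((p, g, *([np.nan] * 5)))
                continue
            q = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
            rows.append((p, g, *q))
    return pd.DataFrame(
        rows, columns=["protein", "group", "min", "q1", "median", "q3", "max"]
    )
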