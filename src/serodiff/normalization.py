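"""Normalization chain: log2 transform, per-sample median centering, and
cross-sample quantile ("rank") normalization.

Quantile normalization replaces each value by the cohort-average value at the
same within-sample quantile: within each sample the non-missing values are
ranked (ties averaged), the rank r of m observations maps to probability
p = (r - 1)/(m - 1), and the replacement is the mean over all samples of
their linearly interpolated empirical quantile at p.  For complete matrices
with equal counts this reduces to classic quantile normalization (replace the
r-th ranked value by the mean of all samples' r-th ranked values) and any two
samples end up with identical sorted value multisets.  Missing values are
excluded from ranking and preserved in place.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from serodiff.matrix import (
    STAGE_LOG2,
    STAGE_MEDIAN,
    STAGE_RANK,
    IntensityMatrix,
)

__all__ = ["log2_transform", "median_normalize", "rank_normalize", "normalize_chain"]


def _check_nonempty_columns(matrix: IntensityMatrix) -> None:
    counts = matrix.data.notna().sum(axis=0)
    empty = counts[counts == 0].index.tolist()
    if empty:
        raise ValueError(f"samples with no non-missing values: {empty}")


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace every non-missing value by its base-2 logarithm.

    Raw relative-quantitation ratios must be strictly positive; applying the
    transform twice is refused via the recorded stage flag.
    """
    if matrix.has_stage(STAGE_LOG2):
        raise ValueError("matrix is already log2-scaled (double application)")
    values = matrix.data.to_numpy(copy=True)
    bad = np.argwhere(values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {values[i, j]!r} for protein "
            f"{matrix.proteins[i]!r} in sample {matrix.samples[j]!r}"
        )
    return matrix.with_values(np.log2(values), add_stage=STAGE_LOG2)


def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Subtract each sample column's median over non-missing values.

    After application every column's median is 0 (even counts use the
    mean-of-middle-two median).  Idempotent.
    """
    _check_nonempty_columns(matrix)
    values = matrix.data.to_numpy(copy=True)
    medians = np.nanmedian(values, axis=0)
    out = values - medians[None, :]
    stage = None if matrix.has_stage(STAGE_MEDIAN) else STAGE_MEDIAN
    return matrix.with_values(out, add_stage=stage)


def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    n_proteins, n_samples = values.shape
    probs = np.full_like(values, np.nan)
    sorted_cols: list[np.ndarray] = []
    grids: list[np.ndarray] = []
    for j in range(n_samples):
        col = values[:, j]
        obs = ~np.isnan(col)
        m = int(obs.sum())
        r = rankdata(col[obs])  # average ranks for ties
        probs[obs, j] = (r - 1.0) / (m - 1.0) if m > 1 else 0.5
        srt = np.sort(col[obs])
        sorted_cols.append(srt)
        grids.append(np.linspace(0.0, 1.0, m) if m > 1 else np.array([0.5]))

    flat = probs.ravel()
    obs_flat = ~np.isnan(flat)
    ref = np.zeros(obs_flat.sum())
    for srt, grid in zip(sorted_cols, grids):
        ref += np.interp(flat[obs_flat], grid, srt)
    ref /= n_samples

    out = np.full(flat.shape, np.nan)
    out[obs_flat] = ref
    return out.reshape(values.shape)


def _within_protein_ranks(values: np.ndarray) -> np.ndarray:
    """Alternative reading of rank normalization: replace each protein row by
    its centered cross-sample average ranks (non-default)."""
    out = np.full_like(values, np.nan)
    for i in range(values.shape[0]):
        row = values[i]
        obs = ~np.isnan(row)
        m = int(obs.sum())
        if m == 0:
            continue
        out[i, obs] = rankdata(row[obs]) - (m + 1) / 2.0
    return out


def rank_normalize(matrix: IntensityMatrix, method: str = "quantile") -> IntensityMatrix:
    """Rank normalization across the data set.

    ``method="quantile"`` (default) performs cross-sample quantile
    normalization as described in the module docstring; ``method=
    "within_protein"`` instead replaces each protein row by centered
    cross-sample ranks (an alternative reading, off the default path).
    """
    _check_nonempty_columns(matrix)
    values = matrix.data.to_numpy(copy=True)
    if method == "quantile":
        out = _quantile_normalize(values)
    elif method == "within_protein":
        out = _within_protein_ranks(values)
    else:
        raise ValueError(f"unknown rank-normalization method {method!r}")
    stage = None if matrix.has_stage(STAGE_RANK) else STAGE_RANK
    return matrix.with_values(out, add_stage=stage)


def normalize_chain(
    matrix: IntensityMatrix,
    log2: bool = True,
    median: bool = True,
    rank: bool = True,
    rank_method: str = "quantile",
) -> IntensityMatrix:
    """Apply the full normalization chain in order.

    ``log2=False`` accepts matrices whose values are already on the log2
    scale (as relative-quantitation ratios exported by upstream software may
    be); matrices carrying the ``log2`` stage flag skip the transform
    automatically.
    """
    if log2 and not matrix.has_stage(STAGE_LOG2):
        matrix = log2_transform(matrix)
    if median:
        matrix = median_normalize(matrix)
    if rank:
        matrix = rank_normalize(matrix, method=rank_method)
    return matrix
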