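"""Cross-validated Welch-test intersection selection of DE proteins.

A protein is called differentially expressed when it is quantifiable (at
least ``min_obs_per_group`` non-missing values per group in every tested
set) and its Welch two-sided p-value is below ``alpha`` in *every* fold of
the plan — an intersection rule far more stringent than a single test, whose
per-protein false-positive probability is bounded by the single-fold level
alpha.  No multiple-testing correction is applied by the rule itself; a
Benjamini-Hochberg column over the per-protein worst-case (max) fold
p-values is emitted for information only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from serodiff.cohort import validate_design
from serodiff.folds import FoldPlan
from serodiff.matrix import IntensityMatrix
from serodiff.welch import welch_arrays

__all__ = ["select_de", "partition_up_down"]


def _group_stats(values: np.ndarray, cols: np.ndarray):
    sub = values[:, cols]
    n = (~np.isnan(sub)).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=1)
        var = np.nanvar(sub, axis=1, ddof=1)
    mean = np.where(n > 0, mean, np.nan)
    var = np.where(n > 1, var, np.nan)
    return mean, var, n


def select_de(
    matrix: IntensityMatrix,
    design: pd.DataFrame,
    folds: FoldPlan,
    alpha: float = 0.01,
    min_obs_per_group: int = 2,
    test_scope: str = "train",
) -> pd.DataFrame:
    """Run the per-fold Welch tests and apply the intersection rule.

    ``test_scope`` picks which samples each fold tests: ``"train"``
    (default; the 30-sample training sets support a t-test), ``"validation"``
    (the small held-out sets), or ``"all"`` (both sets per fold must pass,
    the strictest reading).

    Returns the DE table with one row per protein: quantifiability, overall
    per-group mean/SD/n computed on all samples, per-fold p-value columns,
    the max fold p, the DE decision, the direction of the difference
    (``up`` = higher in CCA), and an informational BH-adjusted q-value.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_obs_per_group < 2:
        raise ValueError(f"min_obs_per_group must be >= 2, got {min_obs_per_group}")
    if test_scope not in ("train", "validation", "all"):
        raise ValueError(f"unknown test_scope {test_scope!r}")
    if folds.k < 1 or not folds.folds:
        raise ValueError("empty fold plan")
    validate_design(design)
    folds.validate(design)
    if set(matrix.samples) != set(design["sample_id"]):
        raise ValueError("matrix samples do not match the design")

    values = matrix.data.to_numpy()
    col_index = {s: j for j, s in enumerate(matrix.samples)}
    group_of = dict(zip(design["sample_id"], design["group"]))

    def group_cols(sample_ids):
        cca = np.array([col_index[s] for s in sample_ids if group_of[s] == "CCA"], int)
        bbtd = np.array([col_index[s] for s in sample_ids if group_of[s] == "BBTD"], int)
        return cca, bbtd

    tested: list[tuple[str, tuple[str, ...]]] = []
    for i, (train, val) in enumerate(folds.folds):
        if test_scope in ("train", "all"):
            tested.append((f"p_fold{i + 1}_train" if test_scope == "all" else f"p_fold{i + 1}", train))
        if test_scope in ("validation", "all"):
            tested.append((f"p_fold{i + 1}_val" if test_scope == "all" else f"p_fold{i + 1}", val))

    out = pd.DataFrame(index=matrix.data.index)
    out.index.name = "protein"
    quantifiable = np.ones(matrix.n_proteins, dtype=bool)
    p_cols = []
    for name, sample_ids in tested:
        cca_cols, bbtd_cols = group_cols(sample_ids)
        ma, va, na = _group_stats(values, cca_cols)
        mb, vb, nb = _group_stats(values, bbtd_cols)
        quantifiable &= (na >= min_obs_per_group) & (nb >= min_obs_per_group)
        _, _, p = welch_arrays(ma, va, na, mb, vb, nb)
        out[name] = p
        p_cols.append(name)

    pmat = out[p_cols].to_numpy()
    with np.errstate(invalid="ignore"):
        max_p = np.nanmax(pmat, axis=1)
        all_below = np.all(pmat < alpha, axis=1)
    max_p = np.where(quantifiable, max_p, np.nan)

    all_cca, all_bbtd = group_cols(list(design["sample_id"]))
    ma, va, na = _group_stats(values, all_cca)
    mb, vb, nb = _group_stats(values, all_bbtd)
    diff = ma - mb

    out.insert(0, "quantifiable", quantifiable)
    out["mean_cca"] = ma
    out["sd_cca"] = np.sqrt(va)
    out["n_cca"] = na
    out["mean_bbtd"] = mb
    out["sd_bbtd"] = np.sqrt(vb)
    out["n_bbtd"] = nb
    out["max_fold_p"] = max_p
    out["is_de"] = quantifiable & all_below
    out["direction"] = np.where(diff > 0, "up", np.where(diff < 0, "down", ""))

    out["bh_q"] = np.nan
    mask = quantifiable & ~np.isnan(max_p)
    if mask.any():
        out.loc[mask, "bh_q"] = multipletests(max_p[mask], method="fdr_bh")[1]
    return out


def partition_up_down(table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split the DE proteins by direction of the group-mean difference.

    Returns ``(up, down)`` protein-id lists (up = higher in CCA), each
    ordered by max fold p ascending (most significant first).
    """
    de = table[table["is_de"]].sort_values("max_fold_p", kind="mergesort")
    up = de.index[de["direction"] == "up"].tolist()
    down = de.index[de["direction"] == "down"].tolist()
    return up, down
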