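"""Cohort design I/O, clinical cohort comparisons, and summary-table audits.

The clinical comparison mirrors the standard case-control table of a serum
biomarker study: counts compared by Pearson chi-squared, an approximately
normal variable (age) by Student's t-test, and skewed range-censored assay
variables (CEA, CA19-9) by the Mann-Whitney U test.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from serodiff.welch import welch_from_summary

GROUPS = ("CCA", "BBTD")
SEXES = ("male", "female")
DESIGN_COLUMNS = ["sample_id", "group", "sex", "age", "cea", "ca19_9"]

#: Default variable -> test mapping; overridable in compare_cohorts.
DEFAULT_TEST_MAP: Mapping[str, str] = {
    "sex": "chi2",
    "age": "student_t",
    "cea": "mannwhitney",
    "ca19_9": "mannwhitney",
}


class DesignParseError(ValueError):
    """The design CSV does not conform to the dialect."""


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignParseError(f"design missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise DesignParseError(f"duplicate sample ids: {dup}")
    bad = design.loc[~design["group"].isin(GROUPS)]
    if len(bad):
        raise DesignParseError(
            f"unknown group labels {sorted(bad['group'].unique())}; "
            f"expected one of {GROUPS}"
        )
    bad = design.loc[~design["sex"].isin(SEXES)]
    if len(bad):
        raise DesignParseError(
            f"unknown sex labels {sorted(bad['sex'].unique())}; "
            f"expected one of {SEXES}"
        )


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a cohort design CSV, enforcing strict group/sex labels.

    Errors report the first offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "sex": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignParseError(f"{path}: missing columns {missing}")
    # header is line 1, first data row line 2
    for col, allowed in (("group", GROUPS), ("sex", SEXES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DesignParseError(
                f"{path}: line {row + 2}: unknown {col} label "
                f"{df[col].iloc[row]!r}; expected one of {allowed}"
            )
    dup = df["sample_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DesignParseError(
            f"{path}: line {row + 2}: duplicate sample id "
            f"{df['sample_id'].iloc[row]!r}"
        )
    return df[DESIGN_COLUMNS]


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design)
    design[DESIGN_COLUMNS].to_csv(path, index=False)


def _describe_numeric(x: np.ndarray, style: str) -> str:
    if style == "mean_sd":
        return f"{np.mean(x):.1f} ± {np.std(x, ddof=1):.1f}"
    return f"{np.median(x):.2f} ({np.min(x):.2f}-{np.max(x):.2f})"


def compare_cohorts(
    design: pd.DataFrame,
    alpha: float = 0.05,
    test_map: Mapping[str, str] | None = None,
    yates: bool = False,
) -> pd.DataFrame:
    """Compare clinical variables between the CCA and BBTD groups.

    Returns a table with one row per variable: the test applied, its
    statistic, the two-sided p-value, per-group descriptors, and a
    significance flag at ``alpha``.  A variable constant in both groups is
    reported with an undefined (NaN) statistic rather than raising.

    The Mann-Whitney U test uses the exact null distribution when the
    combined sample size is at most 20 and the tie-corrected normal
    approximation otherwise.
    """
    validate_design(design)
    test_map = dict(DEFAULT_TEST_MAP, **(test_map or {}))
    cca = design[design["group"] == "CCA"]
    bbtd = design[design["group"] == "BBTD"]
    if len(cca) == 0 or len(bbtd) == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for var, test in test_map.items():
        if test == "chi2":
            counts = np.array(
                [
                    [(cca["sex"] == s).sum() for s in SEXES],
                    [(bbtd["sex"] == s).sum() for s in SEXES],
                ]
            )
            desc_a = f"{counts[0, 0]}:{counts[0, 1]}"
            desc_b = f"{counts[1, 0]}:{counts[1, 1]}"
            if (counts.sum(axis=0) == 0).any():
                stat, p = np.nan, np.nan
            else:
                stat, p, _, _ = stats.chi2_contingency(counts, correction=yates)
            rows.append((var, "Pearson chi-squared", stat, p, desc_a, desc_b))
            continue

        a = cca[var].to_numpy(dtype=float)
        b = bbtd[var].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            name = "Student t" if test == "student_t" else "Mann-Whitney U"
            rows.append(
                (var, name, np.nan, np.nan, _describe_numeric(a, "mean_sd"),
                 _describe_numeric(b, "mean_sd"))
            )
            continue
        if test == "student_t":
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append(
                (var, "Student t", stat, p,
                 _describe_numeric(a, "mean_sd"), _describe_numeric(b, "mean_sd"))
            )
        elif test == "mannwhitney":
            method = "exact" if len(a) + len(b) <= 20 else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append(
                (var, "Mann-Whitney U", res.statistic, res.pvalue,
                 _describe_numeric(a, "median_range"),
                 _describe_numeric(b, "median_range"))
            )
        else:
            raise ValueError(f"unknown test {test!r} for variable {var!r}")

    out = pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p", "cca", "bbtd"]
    )
    out["significant"] = out["p"] < alpha
    return out


def parse_printed_p(value) -> tuple[float, bool]:
    """Parse a reported p-value that may be a bound like ``"<0.001"``.

    Returns ``(value, is_upper_bound)``.
    """
    if isinstance(value, str):
        value = value.strip()
        if value.startswith("<"):
            return float(value[1:]), True
        return float(value), False
    return float(value), False


def audit_summary_table(
    table: pd.DataFrame,
    n_a: int = 19,
    n_b: int = 17,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Recompute Welch p-values from a published-style summary table.

    ``table`` needs columns ``label, mean_a, sd_a, mean_b, sd_b, printed_p``
    (group A = CCA, group B = BBTD) and may carry a ``direction`` column with
    values ``up``/``down``.  Each row is re-evaluated with the Welch test from
    summary statistics at group sizes ``n_a``/``n_b``; the audit flags rows
    whose recomputed p is not below ``alpha``, rows whose printed p violates
    ``alpha``, and rows whose direction label contradicts the sign of
    ``mean_a - mean_b``.  Malformed rows are reported in the ``error`` column
    and processing continues.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("group sizes must be >= 2")
    rows = []
    for _, r in table.iterrows():
        rec = {
            "label": r["label"],
            "t": np.nan,
            "df": np.nan,
            "recomputed_p": np.nan,
            "flag_recomputed_p": False,
            "flag_printed_p": False,
            "flag_direction": False,
            "error": "",
        }
        try:
            res = welch_from_summary(
                float(r["mean_a"]), float(r["sd_a"]), n_a,
                float(r["mean_b"]), float(r["sd_b"]), n_b,
            )
            rec.update(t=res.t, df=res.df, recomputed_p=res.p)
            rec["flag_recomputed_p"] = not res.p < alpha
            diff = float(r["mean_a"]) - float(r["mean_b"])
            if "direction" in table.columns and r["direction"] in ("up", "down"):
                expected = "up" if diff > 0 else "down"
                rec["flag_direction"] = r["direction"] != expected
        except (TypeError, ValueError) as exc:
            rec["error"] = str(exc)
        try:
            p_val, is_bound = parse_printed_p(r["printed_p"])
            rec["printed_p"] = p_val
            rec["printed_p_is_bound"] = is_bound
            rec["flag_printed_p"] = p_val > alpha if is_bound else not p_val < alpha
        except (TypeError, ValueError) as exc:
            rec["error"] = (rec["error"] + "; " if rec["error"] else "") + str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("serodiff").joinpath("data", name)))


def reference_summary_table() -> pd.DataFrame:
    """The packaged reference table of 93 serum proteins reported as
    differentially abundant between CCA (n=19) and BBTD (n=17): group means
    +/- SD on the normalized log2 scale, the reported p-value (possibly a
    bound such as ``<0.001``), and the reported direction."""
    df = pd.read_csv(_data_path("cca_bbtd_de_summary.tsv"), sep="\t", dtype=str)
    for col in ("mean_a", "sd_a", "mean_b", "sd_b"):
        df[col] = df[col].astype(float)
    return df


def reference_cohort_table() -> pd.DataFrame:
    """The packaged clinical summary of the 36-patient reference cohort."""
    return pd.read_csv(_data_path("cca_bbtd_cohort_summary.tsv"), sep="\t")
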