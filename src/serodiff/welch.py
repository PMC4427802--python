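"""Two-sample Welch t-test, from raw values or from summary statistics.

The Welch (unequal-variance) t statistic for groups A and B is

    t = (mean_A - mean_B) / sqrt(s_A^2 / n_A + s_B^2 / n_B)

with Welch-Satterthwaite degrees of freedom

    df = (s_A^2/n_A + s_B^2/n_B)^2 /
         [ (s_A^2/n_A)^2 / (n_A - 1) + (s_B^2/n_B)^2 / (n_B - 1) ]

and a two-sided p-value from the t distribution at df.  The summary-statistic
form exists so published tables reporting only mean +/- SD and group sizes
can be audited; fed a sample's own mean/SD/n it reproduces the raw-data test
exactly.

Degenerate samples follow a limiting convention: when both group variances
are zero the test is decided by the means alone (equal means -> p = 1,
distinct means -> perfect separation, p = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["WelchResult", "welch_test", "welch_from_summary", "welch_arrays"]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def welch_arrays(
    mean_a: np.ndarray,
    var_a: np.ndarray,
    n_a: np.ndarray,
    mean_b: np.ndarray,
    var_b: np.ndarray,
    n_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test from per-group means, variances (ddof=1) and
    counts.  Returns ``(t, df, p)`` arrays; the zero-variance convention is
    applied elementwise.  Entries with ``n < 2`` in either group yield NaN.
    """
    mean_a = np.asarray(mean_a, dtype=float)
    var_a = np.asarray(var_a, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    var_b = np.asarray(var_b, dtype=float)
    n_b = np.asarray(n_b, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        va = var_a / n_a
        vb = var_b / n_b
        se2 = va + vb
        diff = mean_a - mean_b
        t = diff / np.sqrt(se2)
        df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    ok = (n_a >= 2) & (n_b >= 2)
    degenerate = ok & (se2 == 0)
    if np.any(degenerate):
        both_df = n_a + n_b - 2
        equal = degenerate & (diff == 0)
        apart = degenerate & (diff != 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        df = np.where(degenerate, both_df, df)
        with np.errstate(invalid="ignore"):
            t = np.where(apart, np.sign(diff) * np.inf, t)
        p = np.where(apart, 0.0, p)
    t = np.where(ok, t, np.nan)
    df = np.where(ok, df, np.nan)
    p = np.where(ok, p, np.nan)
    return t, df, p


def welch_test(values_a, values_b) -> WelchResult:
    """Welch t-test on two raw samples (NaNs dropped).

    Raises ``ValueError`` when either group has fewer than two non-missing
    observations; callers screening proteins for quantifiability should
    check counts first rather than catch this.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs >= 2 non-missing observations, got {a.size} and {b.size}"
        )
    t, df, p = welch_arrays(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=int(a.size), n_b=int(b.size),
    )


def welch_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> WelchResult:
    """Welch t-test from group summary statistics (mean, SD, n).

    SDs must be strictly positive and group sizes at least 2; this is the
    entry point for auditing published mean +/- SD tables.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError(f"SDs must be positive, got sd_a={sd_a}, sd_b={sd_b}")
    if n_a < 2 or n_b < 2:
        raise ValueError(f"group sizes must be >= 2, got n_a={n_a}, n_b={n_b}")
    t, df, p = welch_arrays(
        mean_a, sd_a**2, n_a, mean_b, sd_b**2, n_b
    )
    return WelchResult(
        t=float(t), df=float(df), p=float(p),
        mean_a=float(mean_a), mean_b=float(mean_b),
        sd_a=float(sd_a), sd_b=float(sd_b), n_a=int(n_a), n_b=int(n_b),
    )
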