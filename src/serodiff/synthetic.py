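"""Synthetic cohorts and intensity matrices for pipeline validation.

Simulation starts at the protein-quantitation matrix: no spectra, peptides or
identification error are modeled.  Values are generated directly on the log2
scale as

    x_ij = baseline_i + effect_i * [group_j == CCA] + shift_j + eps_ij

with protein baselines Normal(0, baseline_sd), within-group noise
eps_ij ~ Normal(0, sigma_i), and a per-sample additive shift
Normal(0, sample_shift_sd) emulating loading/instrument drift — the
distortion per-sample median normalization is meant to remove.  A configured
fraction of proteins carries a true group effect, split between positive
(CCA-up) and negative directions, with magnitudes uniform on
[effect_low, effect_high].

Clinical covariates (age, sex, CEA, CA19-9) are drawn to match the
demographics of the 19 CCA / 17 BBTD serum cohort this package's defaults
emulate; the skewed tumor markers are lognormal and clipped to the assay
reporting ranges (CA19-9 saturates at 10000 ng/mL).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from serodiff.config import (
    _CA19_9_LOG_SD,
    _CEA_LOG_SD,
    REFERENCE_CLINICAL,
    SimulationConfig,
)
from serodiff.matrix import STAGE_LOG2, IntensityMatrix

TRUTH_COLUMNS = ["protein", "is_de", "effect", "baseline", "sigma"]


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent per-stage streams derived from the single simulation seed
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw a cohort design table (one row per sample).

    Ages are normal with the reference group means/SDs; CEA and CA19-9 are
    lognormal around the reference medians and clipped to the assay ranges.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    frames = []
    for group, n in (("CCA", config.n_cca), ("BBTD", config.n_bbtd)):
        ref = REFERENCE_CLINICAL[group]
        male_p = ref["male_female"][0] / sum(ref["male_female"])
        sex = np.where(rng.random(n) < male_p, "male", "female")
        age = rng.normal(ref["age_mean"], ref["age_sd"], n).round(1)
        cea = np.exp(rng.normal(np.log(ref["cea_median"]), _CEA_LOG_SD, n))
        cea = np.clip(cea, *ref["cea_range"]).round(2)
        ca19 = np.exp(rng.normal(np.log(ref["ca19_9_median"]), _CA19_9_LOG_SD, n))
        ca19 = np.clip(ca19, *ref["ca19_9_range"]).round(2)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [f"{group}{i + 1:02d}" for i in range(n)],
                    "group": group,
                    "sex": sex,
                    "age": age,
                    "cea": cea,
                    "ca19_9": ca19,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    proteins = [f"P{i + 1:04d}" for i in range(n)]
    baseline = rng.normal(0.0, config.baseline_sd, n)
    sigma = rng.uniform(config.sd_low, config.sd_high, n)
    effect = np.zeros(n)
    n_de = config.n_de
    if n_de:
        de_idx = rng.choice(n, size=n_de, replace=False)
        n_up = round(config.frac_up * n_de)
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        mags = rng.uniform(config.effect_low, config.effect_high, n_de)
        effect[de_idx] = signs * mags
    return pd.DataFrame(
        {
            "protein": proteins,
            "is_de": effect != 0.0,
            "effect": effect,
            "baseline": baseline,
            "sigma": sigma,
        }
    )


def simulate_matrix(
    config: SimulationConfig, design: pd.DataFrame
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Draw a log2 intensity matrix and its ground-truth record.

    Returns the matrix (stage ``log2`` pre-applied — values are already on
    the log scale and may be negative) and a per-protein truth table with
    columns ``protein, is_de, effect, baseline, sigma`` where ``effect`` is
    the CCA-minus-BBTD group-mean difference in log2 units (0 for non-DE
    proteins).

    Missingness is MCAR at ``missing_rate`` by default; ``missing_mode=
    "censored"`` makes the dropout probability decrease linearly with the
    value's overall rank (low-abundance values drop out more), preserving
    the expected rate.
    """
    config.validate()
    n_samples = config.n_cca + config.n_bbtd
    if len(design) != n_samples:
        raise ValueError(
            f"design has {len(design)} samples, config expects {n_samples}"
        )
    counts = design["group"].value_counts()
    if counts.get("CCA", 0) != config.n_cca or counts.get("BBTD", 0) != config.n_bbtd:
        raise ValueError("design group counts do not match config")

    truth = _truth(config, _rng(config.seed, 1))
    rng = _rng(config.seed, 2)

    is_cca = (design["group"] == "CCA").to_numpy()
    shift = rng.normal(0.0, config.sample_shift_sd, n_samples)
    noise = rng.normal(0.0, 1.0, (config.n_proteins, n_samples))
    values = (
        truth["baseline"].to_numpy()[:, None]
        + truth["effect"].to_numpy()[:, None] * is_cca[None, :]
        + shift[None, :]
        + noise * truth["sigma"].to_numpy()[:, None]
    )

    if config.missing_rate > 0:
        if config.missing_mode == "mcar":
            mask = rng.random(values.shape) < config.missing_rate
        else:
            # left-censored: dropout prob = 2 * rate * (1 - global rank frac)
            order = values.ravel().argsort().argsort()
            frac = order.reshape(values.shape) / (values.size - 1)
            prob = np.clip(2.0 * config.missing_rate * (1.0 - frac), 0.0, 1.0)
            mask = rng.random(values.shape) < prob
        values = np.where(mask, np.nan, values)

    df = pd.DataFrame(
        values, index=truth["protein"].tolist(), columns=design["sample_id"].tolist()
    )
    return IntensityMatrix(df, (STAGE_LOG2,)), truth
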