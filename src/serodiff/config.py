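"""Configuration objects shared across the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


#: Clinical parameters of the 19 CCA / 17 BBTD discovery cohort the simulator
#: emulates: age in years (mean, SD), serum tumor markers CEA (U/mL) and
#: CA19-9 (ng/mL) as (median, assay min, assay max), and male:female counts.
REFERENCE_CLINICAL = {
    "CCA": {
        "n": 19,
        "age_mean": 60.9,
        "age_sd": 13.0,
        "cea_median": 9.87,
        "cea_range": (1.47, 410.40),
        "ca19_9_median": 4355.50,
        "ca19_9_range": (0.60, 10000.0),
        "male_female": (10, 9),
    },
    "BBTD": {
        "n": 17,
        "age_mean": 52.6,
        "age_sd": 13.0,
        "cea_median": 8.70,
        "cea_range": (0.62, 118.30),
        "ca19_9_median": 48.03,
        "ca19_9_range": (0.60, 10000.0),
        "male_female": (10, 7),
    },
}

# Log-scale spread of the skewed serum markers, chosen so simulated ranges
# span the assay ranges above at the cohort sizes used (CA19-9 saturates at
# the 10000 upper assay limit in a visible fraction of CCA draws).
_CEA_LOG_SD = 1.2
_CA19_9_LOG_SD = 2.2


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort + intensity-matrix generator.

    All intensity-scale quantities are in log2 units.  Defaults emulate the
    discovery setting the pipeline targets: 19 CCA vs 17 BBTD sera, 951
    quantified proteins, roughly a tenth of them carrying a true group
    effect whose magnitude spans the range reported for serum DE proteins
    (0.25-1.7 log2 units) with within-group SDs of 0.1-0.9.
    """

    n_cca: int = 19
    n_bbtd: int = 17
    n_proteins: int = 951
    frac_de: float = 0.1
    effect_low: float = 0.25
    effect_high: float = 1.7
    sd_low: float = 0.1
    sd_high: float = 0.9
    baseline_sd: float = 1.0
    sample_shift_sd: float = 0.3
    missing_rate: float = 0.05
    missing_mode: Literal["mcar", "censored"] = "mcar"
    frac_up: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_cca < 2:
            raise ConfigError(f"n_cca must be >= 2, got {self.n_cca}")
        if self.n_bbtd < 2:
            raise ConfigError(f"n_bbtd must be >= 2, got {self.n_bbtd}")
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if not 0.0 <= self.frac_up <= 1.0:
            raise ConfigError(f"frac_up must be in [0, 1], got {self.frac_up}")
        if self.effect_low < 0 or self.effect_low > self.effect_high:
            raise ConfigError(
                "effect_low must satisfy 0 <= effect_low <= effect_high, got "
                f"effect_low={self.effect_low}, effect_high={self.effect_high}"
            )
        if self.sd_low <= 0 or self.sd_low > self.sd_high:
            raise ConfigError(
                "sd_low must satisfy 0 < sd_low <= sd_high, got "
                f"sd_low={self.sd_low}, sd_high={self.sd_high}"
            )
        if self.baseline_sd < 0:
            raise ConfigError(f"baseline_sd must be >= 0, got {self.baseline_sd}")
        if self.sample_shift_sd < 0:
            raise ConfigError(
                f"sample_shift_sd must be >= 0, got {self.sample_shift_sd}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        if self.missing_mode not in ("mcar", "censored"):
            raise ConfigError(
                f"missing_mode must be 'mcar' or 'censored', got {self.missing_mode!r}"
            )
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")

    @property
    def n_de(self) -> int:
        return round(self.frac_de * self.n_proteins)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg
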