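import numpy as np
import pandas as pd
import pytest

from serodiff import (
    IntensityMatrix,
    SimulationConfig,
    build_folds,
    normalize_chain,
    simulate_cohort,
    simulate_matrix,
)


@pytest.fixture(scope="session")
def default_design():
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated data set with strong effects, shared across tests."""
    cfg = SimulationConfig(
        seed=11, n_proteins=80, frac_de=0.125,
        effect_low=1.2, effect_high=1.7, sd_low=0.2, sd_high=0.5,
    )
    design = simulate_cohort(cfg)
    matrix, truth = simulate_matrix(cfg, design)
    return cfg, design, matrix, truth


@pytest.fixture(scope="session")
def small_normalized(small_sim):
    cfg, design, matrix, truth = small_sim
    return normalize_chain(matrix)


@pytest.fixture(scope="session")
def small_folds(small_sim):
    _, design, _, _ = small_sim
    return build_folds(design, k=6, mode="partition", seed=11)


def make_matrix(values, proteins=None, samples=None, stages=()):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return IntensityMatrix(
        pd.DataFrame(values, index=proteins, columns=samples), tuple(stages)
    )
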