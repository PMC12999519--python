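"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

import numpy as np
import pandas as pd
import pytest

from convorg.preprocess import filter_low_expressed, tmm_normalize
from convorg.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=400,
        n_forms=4,
        individuals_per_form=2,
        control_individuals=4,
        diffs_per_line=2,
        n_modules=3,
        module_size_range=(20, 30),
        cnv_genes_per_form=6,
        n_regulators=4,
        n_downstream_modules=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_expr(small_cohort):
    cohort, truth = small_cohort
    filtered = filter_low_expressed(cohort)
    return tmm_normalize(filtered), filtered.samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_counts(rng):
    """Counts with heterogeneous depths, no structure."""
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.1, size=(300, 8)),
        index=[f"G{i:04d}" for i in range(300)],
        columns=[f"s{i}" for i in range(8)],
    )
    return counts
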