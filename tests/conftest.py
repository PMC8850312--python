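import numpy as np
import pandas as pd
import pytest

from mrmediate import (
    CohortSimConfig,
    GwasSimConfig,
    simulate_cohort,
    simulate_gwas,
)
from mrmediate.synthetic_data import _five_subject_cox, _three_snp_records


@pytest.fixture(scope="session")
def three_snp_pair():
    """Deterministic 3-variant exposure/outcome record pair (one allele swap)."""
    return _three_snp_records()


@pytest.fixture(scope="session")
def five_subject_cox():
    return _five_subject_cox()


@pytest.fixture(scope="session")
def effect_table():
    """50 instruments under a causal effect of 0.2, no pleiotropy."""
    return simulate_gwas(GwasSimConfig(n_snps=50, true_theta=0.2, seed=11))


@pytest.fixture(scope="session")
def null_table():
    """50 instruments with no causal effect."""
    return simulate_gwas(GwasSimConfig(n_snps=50, true_theta=0.0, seed=12))


@pytest.fixture(scope="session")
def default_cohort():
    """One default cohort draw: n = 20,000, ~1% cumulative incidence."""
    return simulate_cohort(CohortSimConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Smaller, event-enriched cohort for structural (non-recovery) checks."""
    return simulate_cohort(
        CohortSimConfig(n_subjects=6000, baseline_rate=4e-3, seed=43)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
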