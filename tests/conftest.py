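import numpy as np
import pytest

import agearch as a


@pytest.fixture(scope="session")
def small_genotypes():
    return a.simulate_genotypes(300, 80, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def linear_sim():
    """Linear liability-threshold simulation at the canonical parameters, desk n."""
    return a.simulate_linear_threshold(50_000, h2=0.3, n_bins=5, bin_fraction=0.02, seed=101)


@pytest.fixture(scope="session")
def ea_sim():
    return a.simulate_ea_threshold(
        50_000, h2=0.3, n_bins=5, bin_fraction=0.02, increment_var=0.05, seed=101
    )


@pytest.fixture(scope="session")
def marker_cohort():
    """Cohort with liability-loaded biomarker traits and one disease (QRS-ready)."""
    geno = a.simulate_genotypes(6000, 400, seed=21)
    cfg = a.CohortConfig(
        traits=[
            a.TraitSpec(f"marker_{i}", loads_on="dz", loading=0.5, measurement_error_var=0.1)
            for i in range(4)
        ]
        + [a.TraitSpec(f"noise_{i}", h2=0.2) for i in range(4)],
        diseases=[a.DiseaseSpec("dz", h2=0.3, bin_fraction=0.04)],
        medication_flags={"hypertension_med": 0.2},
    )
    table, states = a.simulate_cohort(geno, cfg, seed=22)
    return geno, table, states
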