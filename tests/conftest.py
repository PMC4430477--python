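import numpy as np
import pytest

from multihet import het, strat
from multihet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated cohort shared by read-only tests."""
    cfg = SimulationConfig(n_individuals=400, n_snps=4000,
                           baseline_prevalence=0.03, n_periods=8,
                           missing_rate=0.002, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Het profile + eigenvectors for the shared cohort."""
    c = small_cohort
    strata = [het.autosomal_stratum(c.annotation),
              het.define_genic_stratum(c.annotation, c.genes),
              het.nonsynonymous_stratum(c.annotation)]
    profile = het.compute_het_profile(c.genotypes, strata)
    eig = strat.compute_eigenvectors(c.genotypes)
    samples = strat.attach_eigenvectors(c.samples, eig)
    return {"cohort": c, "strata": strata, "profile": profile,
            "eig": eig, "samples": samples}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
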