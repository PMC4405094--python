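import numpy as np
import pytest

import wildarch.simulate as sim


@pytest.fixture(scope="session")
def small_pop():
    """A small pedigreed population shared by format and GRM tests."""
    cfg = sim.SimConfig(
        n_founders=60,
        n_years=8,
        chromosomes=[(80, 40.0), (60, 30.0), (40, 20.0)],
        seed=11,
        polygenic_h2=0.3,
        random_effect_variances={"residual": 0.7},
        repeat_rate=1.5,
    )
    return sim.simulate_population(cfg)


@pytest.fixture(scope="session")
def qtl_pop():
    """Population with a planted additive QTL and repeated measures."""
    cfg = sim.SimConfig(
        n_founders=150,
        n_years=10,
        chromosomes=[(150, 50.0)] * 3,
        seed=21,
        qtl_specs=[sim.QtlSpec(1, target_maf=0.1, additive_effect=0.6)],
        polygenic_h2=0.3,
        random_effect_variances={"residual": 0.7},
        repeat_rate=1.0,
    )
    pop = sim.simulate_population(cfg)
    pheno = sim.simulate_trait_and_phenotypes(pop)
    return pop, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
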