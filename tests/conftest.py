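import numpy as np
import pytest

from rarefam.datasets import cep41_case_control
from rarefam.simulate import SimConfig, rng_streams, simulate_families


@pytest.fixture(scope="session")
def cep41_panel():
    """Worked-example case-control panel (variants, genotypes, cases,
    controls, variants-by-amino-acid-change)."""
    return cep41_case_control()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_family_cohort():
    """Six multiplex families with planted VOIs and decoys."""
    cfg = SimConfig(seed=11, n_families=6)
    streams = rng_streams(cfg.seed)
    return simulate_families(cfg, streams["pedigree"])
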