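import numpy as np
import pandas as pd
import pytest

from orgscope import GroupSpec, TruthConfig, generate_population

INVIVO_GROUPS = (GroupSpec("tumor", "invivo"), GroupSpec("normal", "invivo"))


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused by read/round-trip tests."""
    cfg = TruthConfig(seed=11).small()
    return generate_population(cfg)


@pytest.fixture(scope="session")
def cnv_cohort():
    """Two-arm in-vivo cohort with one planted 2x gain on chr1:30-60 Mb."""
    cfg = TruthConfig(
        n_patients=1,
        cells_per_group=200,
        groups=INVIVO_GROUPS,
        n_genes=2000,
        seed=5,
    )
    return generate_population(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
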