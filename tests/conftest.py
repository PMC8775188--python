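import numpy as np
import pytest

from mapsy import pipeline, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """12 synthetic variants with contexts (session-scoped, fixed seed)."""
    return simulate.synthetic_cohort(12, seed=42)


@pytest.fixture(scope="session")
def small_library(small_cohort):
    """Oligos and species catalogs for the small cohort."""
    variants, contexts = small_cohort
    eligible, oligos, catalogs = pipeline.design_library(variants, contexts)
    return eligible, oligos, catalogs


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
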