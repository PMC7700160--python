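import warnings

import numpy as np
import pytest

from matriscope import CohortConfig, generate_cohort, load_catalog

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort (10 subtypes, 20/subtype, 60 genes) for unit tests."""
    cfg = CohortConfig(
        n_samples_per_subtype=20,
        n_matrisome_genes=60,
        n_planted_markers_per_subtype=3,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The benchmark-condition cohort (5 meta-clusters, 10 subtypes,
    50/subtype, 3 cohort-SD marker effect, unit regulator slope)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def markerless_cohort():
    """Meta-cluster structure only (no planted markers): used to test the
    clustering stage in isolation."""
    cfg = CohortConfig(
        n_samples_per_subtype=20,
        n_matrisome_genes=80,
        n_planted_markers_per_subtype=0,
        n_prognostic_per_subtype=0,
        seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
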