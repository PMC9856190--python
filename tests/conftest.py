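import numpy as np
import pytest

from polraman.preprocess import preprocess_cohort
from polraman.spectra import WavenumberGrid
from polraman.synth import CohortConfig, synth_cohort


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    return WavenumberGrid()


@pytest.fixture(scope="session")
def default_cohort():
    """The study-layout cohort (20/10/12 samples, 10 points each)."""
    return synth_cohort(seed=7)


@pytest.fixture(scope="session")
def default_pre(default_cohort):
    """Preprocessed default cohort, shared across statistical tests."""
    return preprocess_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_pre():
    """A small preprocessed cohort for structural tests (4+2+2 samples)."""
    cfg = CohortConfig(
        n_cancerous=4, n_normal=2, n_paracancerous=2, points_per_sample=2
    )
    return preprocess_cohort(synth_cohort(cfg, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
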