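import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tssensemble import FixtureSpec, GenomeLayout, run_fixture_pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# scikit-learn >= 1.9 warns that SVC(probability=True) will move to
# CalibratedClassifierCV; the probability mechanism itself is unchanged.
warnings.filterwarnings("ignore", message="The `probability` parameter", category=FutureWarning)


@pytest.fixture()
def layout():
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def default_pipeline():
    """The reference end-to-end run: ~2 Mbp fixture, seed 42, 30% hard TSS."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The `probability` parameter", category=FutureWarning
        )
        return run_fixture_pipeline(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def small_fixture_spec():
    """A fast fixture for unit tests (~0.5 Mbp, 120 TSS)."""
    return FixtureSpec(n_chromosomes=4, chromosome_length=120_000, n_tss=120, seed=7)
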