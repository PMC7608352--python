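import pytest

from cnvpheno.codebook import Codebook
from cnvpheno.simulate import CohortParams, simulate_cohort


@pytest.fixture(scope="session")
def codebook():
    return Codebook.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with all decoy kinds active, shared across
    pipeline tests."""
    params = CohortParams(n_participants=20_000, seed=11)
    return params, simulate_cohort(params)
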