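import numpy as np
import pytest

from stratomics.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort158():
    """Default-size synthetic cohort (88 + 70 samples, full feature counts)."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for pipeline-level tests."""
    spec = CohortSpec(seed=11, n_transcripts=150, n_proteins=200, n_metabolites=120,
                      n_affected_t=20, n_affected_p=60, n_affected_m=40,
                      senescence_sizes=(30, 12, 4))
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
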