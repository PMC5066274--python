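import numpy as np
import pytest

from qsmcoloc.cohort import CohortSpec, make_cohort, make_phantom_labels


@pytest.fixture(scope="session")
def layout48():
    """48^3 phantom layout shared by geometry-dependent tests."""
    return make_phantom_labels((48, 48, 48), (0.5, 0.5, 0.5), seed=1)


@pytest.fixture(scope="session")
def smoke_cohort(tmp_path_factory):
    """Tiny 2+2-subject 16^3 cohort written to disk once per session."""
    out = tmp_path_factory.mktemp("cohort") / "smoke"
    cohort = make_cohort(CohortSpec.smoke(seed=5), out)
    return cohort, out


@pytest.fixture(scope="session")
def default_cohort():
    """Default 37-subject cohort, in memory (volumes generated on demand)."""
    return make_cohort(CohortSpec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
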