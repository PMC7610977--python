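import numpy as np
import pytest

from myoprop.geometry import DoAConfig, WorkspaceGeometry


@pytest.fixture(scope="session")
def geometry() -> WorkspaceGeometry:
    return WorkspaceGeometry()


@pytest.fixture(scope="session")
def doa() -> DoAConfig:
    return DoAConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp1_cohort():
    """A default Experiment-1 cohort shared by the slower analysis tests.

    21 subjects of which 2 are non-learners, matching the protocol's
    cohort composition; 19 learners remain after exclusion.
    """
    from myoprop.synth import generate_cohort

    return generate_cohort(1, n_subjects=21, fraction_non_learners=2 / 21, seed=11)
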