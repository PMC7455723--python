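import numpy as np
import pytest

from tce_qsp.calibration import problem_from_study
from tce_qsp.model import SolverSettings
from tce_qsp.reference import reference_cyno
from tce_qsp.synthetic import generate_cyno_study


@pytest.fixture(scope="session")
def ref_cyno():
    return reference_cyno()


@pytest.fixture(scope="session")
def small_study(ref_cyno):
    """Zero-noise single-group 2-dose study: cheap, exactly recoverable."""
    dataset, traces = generate_cyno_study(
        ref_cyno, doses=[1.0], n_per_group=1, noise_cv=0.0, jitter_cv=0.0,
        seed=7, t_end=14.0,
    )
    return dataset, traces


@pytest.fixture(scope="session")
def small_problem(small_study):
    dataset, traces = small_study
    return problem_from_study(dataset, traces, t_end=14.0)


@pytest.fixture(scope="session")
def fast_settings():
    return SolverSettings(rtol=1e-6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
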