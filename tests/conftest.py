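import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    from nanometering import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def lysozyme_problem():
    from nanometering import packaged_filling_config

    return packaged_filling_config("lysozyme")


@pytest.fixture(scope="session")
def doxorubicin_problem():
    from nanometering import packaged_filling_config

    return packaged_filling_config("doxorubicin")


def slab_center_ratio(fo, n_terms: int = 400):
    """Analytic Fourier-series centre concentration of a slab held at c_b on
    both faces, zero initial condition; fo = (D/τ)·t/(T/2)².

    Independent oracle for the numerical filling solver.
    """
    fo = np.atleast_1d(np.asarray(fo, dtype=float))
    n = 2 * np.arange(n_terms) + 1
    sign = (-1.0) ** np.arange(n_terms)
    terms = sign * (4.0 / (np.pi * n)) * np.exp(-((n * np.pi / 2.0) ** 2) * fo[:, None])
    return 1.0 - terms.sum(axis=1)
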