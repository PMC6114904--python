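import pytest

from catchbond import load_table1, sample_dataset
from catchbond.synthetic import ExperimentDesign


@pytest.fixture(scope="session")
def table1():
    """Wild-type best-fit parameters and default environment."""
    return load_table1()


@pytest.fixture(scope="session")
def low_barrier():
    """Barriers scaled to the 4-8 kT range where every oracle is usable."""
    params, env = load_table1()
    return params.replace(E0=8.0, E1=2.0, H=6.0, G=2.0), env


@pytest.fixture(scope="session")
def small_dataset(table1):
    """A 400-record synthetic dataset at the default force design."""
    params, env = table1
    design = ExperimentDesign(n_measurements=400, seed=20240)
    return sample_dataset(design, params, env)


# fast, verified-adequate grids for fitting-heavy tests
FIT_RATE_KW = dict(n_theta=100, n_r=80)
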