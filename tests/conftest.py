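import numpy as np
import pytest

from n2opart import (
    EndmemberSet,
    ProcessFractions,
    default_endmember_set,
    load_endmembers,
    read_steady_table,
)
from n2opart.io import default_endmember_path
from n2opart.synthetic import DEFAULT_NOISE, default_truth


@pytest.fixture(scope="session")
def ems() -> EndmemberSet:
    """Shipped default endmember set (case 1, fungal denitrification)."""
    return load_endmembers()


@pytest.fixture(scope="session")
def table2_records():
    """Treatment-mean records parsed from the shipped fixture table."""
    import importlib.resources as resources
    path = resources.files("n2opart").joinpath("data", "table2_means.csv")
    return read_steady_table(str(path))


@pytest.fixture(scope="session")
def hn_record(table2_records):
    return next(r for r in table2_records if r.treatment == "HN")


@pytest.fixture(scope="session")
def ln_record(table2_records):
    return next(r for r in table2_records if r.treatment == "LN")


@pytest.fixture
def zero_noise():
    """Noise dict with every level set to zero (deterministic forward model)."""
    return {k: 0.0 for k in DEFAULT_NOISE}


@pytest.fixture
def noiseless_hn_truth(zero_noise):
    """An HN-treatment truth whose record reproduces the forward model exactly."""
    return default_truth("HN-clean", "HN", fractions=(0.45, 0.36, 0.12, 0.07),
                         f_red=0.1, noise=zero_noise)


def random_feasible_truth(rng: np.random.Generator, processes, f_red: float,
                          alpha: float = 1.5) -> ProcessFractions:
    """A random point on the simplex as ground-truth fractions."""
    f = rng.dirichlet([alpha] * len(processes))
    return ProcessFractions(processes=tuple(processes),
                            fractions=tuple(float(v) for v in f), f_red=f_red)
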