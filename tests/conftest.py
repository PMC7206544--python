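import numpy as np
import pytest

from trxsim import builtin_solvent, build_fixture, default_q_grid
from trxsim.cli_io import make_fixtures


@pytest.fixture(scope="session")
def q_full():
    """The default display q grid, 0.3-8.0 1/A at 0.01 1/A."""
    return default_q_grid()


@pytest.fixture(scope="session")
def q_coarse():
    """A coarse grid for tests where per-point resolution does not matter."""
    return np.linspace(0.3, 8.0, 78)


@pytest.fixture(scope="session")
def chi3():
    return build_fixture("chi3")


@pytest.fixture(scope="session")
def chi2i():
    return build_fixture("chi2i")


@pytest.fixture(scope="session")
def radical_pair():
    return (build_fixture("chi2"), build_fixture("i_atom"))


@pytest.fixture(scope="session")
def cyclohexane(q_full):
    return builtin_solvent("cyclohexane", q_full)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The packaged offline fixture set, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(out, seed=7)
    return out
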