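import numpy as np
import pytest

from qpeakfit import default_candidates, make_host_fixture


@pytest.fixture(scope="session")
def guests10():
    """The built-in ten-guest candidate library (conformer embedding is the
    expensive step, so share one instance across the whole session)."""
    return default_candidates()


@pytest.fixture()
def host_fixture():
    return make_host_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_cell(rng):
    """A realistic random triclinic cell (moderate aspect ratio and angles)."""
    from qpeakfit import UnitCell

    while True:
        a, b, c = rng.uniform(6.0, 25.0, size=3)
        al, be, ga = rng.uniform(65.0, 115.0, size=3)
        try:
            return UnitCell(a, b, c, al, be, ga)
        except ValueError:
            continue
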