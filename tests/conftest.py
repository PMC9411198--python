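import numpy as np
import pytest

import trapline as tl


@pytest.fixture(scope="session")
def collinear():
    """Three collinear platforms at x = 0, 1, 2."""
    return tl.build_array("line", {"A": (0, 0), "B": (1, 0), "C": (2, 0)})


@pytest.fixture(scope="session")
def unit_square():
    return tl.build_array(
        "square", {"A": (0, 0), "B": (1, 0), "C": (1, 1), "D": (0, 1)}
    )


@pytest.fixture(scope="session")
def double_trapezoid():
    return tl.double_trapezoid()


@pytest.fixture(scope="session")
def pentagon():
    return tl.pentagon()


@pytest.fixture(scope="session")
def z_array():
    return tl.z_array()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
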