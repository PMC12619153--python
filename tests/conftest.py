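import numpy as np
import pytest

from gsmediate import GSDesign, make_design

POCOCK_B = 2.1783  # two-stage two-sided 5% boundary, interim at 50% information


@pytest.fixture(scope="session")
def design_191() -> GSDesign:
    """The n=191/arm design used for the operating-characteristics studies."""
    return make_design(n_max_per_arm=191)


@pytest.fixture(scope="session")
def design_347() -> GSDesign:
    """The n=347/arm design used for the estimation studies."""
    return make_design(n_max_per_arm=347)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250922)
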