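import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from asymperm.landscapes import build_pure_landscape


@pytest.fixture(scope="session")
def double_well():
    """The standard test landscape: wells -40 kJ/mol at +/-2 nm, center +150."""
    return build_pure_landscape(
        adsorption_well_depth=40.0, adsorption_well_pos=2.0, center_G=150.0,
        widths={"center": 0.45, "well": 0.35, "headgroup": 0.25})


@pytest.fixture(scope="session")
def flat_landscape():
    return build_pure_landscape(
        label="flat", adsorption_well_depth=0.0, center_G=0.0,
        headgroup_barrier=0.0)


@pytest.fixture(scope="session")
def demo_trio():
    """Upper/lower pure landscapes with unequal adsorption, plus their blend."""
    from asymperm.demo import demo_landscapes

    return demo_landscapes()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
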