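import numpy as np
import pytest

from lm2r.profiles_io import ReactivityProfile
from lm2r.synthetic import add_construct, make_calibration_fixture


def make_profile(values, label="WT", positions=None, construct_ref="test", **kw):
    values = np.asarray(values, float)
    if positions is None:
        positions = np.arange(1, len(values) + 1)
    return ReactivityProfile(
        construct_ref=construct_ref,
        mutant_label=label,
        positions=positions,
        values=values,
        **kw,
    )


@pytest.fixture(scope="session")
def add_bundle():
    """The bundled riboswitch probed construct with helix registries and
    printed lock-mutant labels."""
    return add_construct()


@pytest.fixture(scope="session")
def toy_calibration():
    """The deterministic toy calibration table (150 helices, seed 0)."""
    return make_calibration_fixture(150, seed=0)
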