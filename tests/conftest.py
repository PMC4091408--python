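import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cell():
    """One synthetic cell stack at the measured regime, shared across tests."""
    from cenquant.synthetic import CellSimSpec, make_cell_stack

    spec = CellSimSpec(seed=0)
    stack, truth = make_cell_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def default_beads():
    from cenquant.synthetic import make_bead_stack

    return make_bead_stack(psf_sigma_xy=100.0, n_beads=49, seed=100)
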