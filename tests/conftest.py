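import numpy as np
import pytest
from hypothesis import settings

from clcsense import CellModel, default_material

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def material():
    return default_material()


@pytest.fixture
def cell_15um_background():
    """15 um cell at the analyte-free effective tilt."""
    return CellModel(gap_um=15.0, tilt_deg=43.0)


@pytest.fixture
def cell_15um_analyte():
    """15 um cell at the tilt induced by adsorbed protein."""
    return CellModel(gap_um=15.0, tilt_deg=48.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
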