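import numpy as np
import pytest

from profenofos_pbk import default_model
from profenofos_pbk.dosimetry import build_cmax_map


@pytest.fixture(scope="session")
def rat_model():
    return default_model("rat", with_bcp=False)


@pytest.fixture(scope="session")
def rat_model_bcp():
    return default_model("rat", with_bcp=True)


@pytest.fixture(scope="session")
def human_model():
    return default_model("human", with_bcp=False)


@pytest.fixture(scope="session")
def rat_cmax_map(rat_model):
    """Coarse but monotone dose->Cmax map reused across tests."""
    return build_cmax_map(rat_model, dose_grid=np.logspace(-4, 3, 20))


@pytest.fixture(scope="session")
def human_cmax_map(human_model):
    return build_cmax_map(human_model, dose_grid=np.logspace(-4, 3, 20))
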