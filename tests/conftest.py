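import numpy as np
import pytest

import nippt
from nippt.simulate import make_str_database


@pytest.fixture(scope="session")
def panel():
    return nippt.default_panel()


@pytest.fixture(scope="session")
def snp_panel(panel):
    return [m for m in panel if m.marker_class == "iiSNP"]


@pytest.fixture(scope="session")
def astr_panel(panel):
    return [m for m in panel if m.marker_class == "A-STR"]


@pytest.fixture(scope="session")
def freqs(panel):
    return nippt.sample_frequencies(panel, np.random.default_rng(7))


@pytest.fixture(scope="session")
def str_db(freqs, panel):
    return make_str_database(freqs, panel)
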