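import numpy as np
import pytest

from exitdose.materials import MaterialPack
from exitdose.pipeline import CaseConfig, run_case


@pytest.fixture(scope="session")
def pack():
    """Shared material pack (triggers one kernel compilation per session)."""
    return MaterialPack()


@pytest.fixture(scope="session")
def small_case_ii(pack):
    """A reduced Case II study shared across transport/pipeline/analysis
    tests (2e5 histories keeps it a few seconds)."""
    case = CaseConfig.preset("II", histories=200_000, seed=42)
    return run_case(case, pack=pack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
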