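import numpy as np
import pytest
from rdkit import RDLogger

from retroedits.extraction import build_vocabulary
from retroedits.fixtures import generate_reactions

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def records16():
    """A small deterministic set of synthetic reactions."""
    return generate_reactions(16, seed=5)


@pytest.fixture(scope="session")
def vocab16(records16):
    return build_vocabulary(records16)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
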