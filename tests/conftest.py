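import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from repatlas.catalog import load_packaged_catalog
from repatlas.rayt_finder import load_seed_proteins


@pytest.fixture(scope="session")
def catalog():
    return load_packaged_catalog()


@pytest.fixture(scope="session")
def seed_protein():
    """(id, sequence) of the packaged synthetic seed RAYT query."""
    (qid, prot), = load_seed_proteins().items()
    return qid, prot


@pytest.fixture()
def rng():
    return np.random.default_rng(20130610)
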