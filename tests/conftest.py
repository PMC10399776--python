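import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from idrcons.seq_regions import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n: int, pid: str = "p") -> ProteinRecord:
    return ProteinRecord(id=pid, sequence="".join(
        np.array(list(AA))[rng.integers(0, 20, size=n)]))


@pytest.fixture
def random_protein_factory():
    return random_protein
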