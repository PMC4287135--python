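import numpy as np
import pytest

from disevo.records import AA20, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20140418)


def random_protein(rng, length, rec_id="p", species=""):
    seq = "".join(rng.choice(list(AA20), size=length))
    return ProteinRecord(id=rec_id, sequence=seq, species=species)


@pytest.fixture
def random_protein_factory():
    return random_protein
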