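import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from ppiboost import builtin_property_tables
from ppiboost.sequence_io import ALPHABET, ProteinSequence


@pytest.fixture(scope="session")
def tables():
    return builtin_property_tables()


@pytest.fixture(scope="session")
def random_sequences():
    """200 random proteins with lengths spanning 31..500, fixed seed."""
    rng = np.random.default_rng(20170808)
    residues = np.array(list(ALPHABET))
    out = []
    for i in range(200):
        n = int(rng.integers(31, 501))
        out.append(
            ProteinSequence(id=f"r{i:03d}", residues="".join(rng.choice(residues, n)))
        )
    return out
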