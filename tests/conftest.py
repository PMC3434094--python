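import numpy as np
import pytest

from mitoevo.io_formats import GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, at=0.5):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def random_genome(rng):
    return GenomeRecord(id="rand", sequence=random_dna(rng, 10000),
                        circular=False)
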