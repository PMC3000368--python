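import numpy as np
import pytest

from islandkit.core import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length, gc=0.5, n_fraction=0.0):
    """IID random nucleotide string with the requested GC content."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(list("ACGT"), size=length, p=p)
    if n_fraction > 0:
        mask = rng.random(length) < n_fraction
        bases[mask] = "N"
    return "".join(bases)


@pytest.fixture
def random_genome(rng):
    return GenomeSequence(
        {
            "chr1": random_sequence(rng, 5000, gc=0.42),
            "chr2": random_sequence(rng, 3000, gc=0.55),
        }
    )
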