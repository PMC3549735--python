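import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kmersig.signatures import ReadSet, supplement_complements


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_reads(rng, n_reads=10, max_len=30, min_len=5, with_n=False, sample_id="s"):
    """Small random read set for oracle comparisons."""
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(min_len, max_len + 1))
        codes = rng.choice(len(alphabet), size=length, p=probs)
        reads.append("".join(alphabet[c] for c in codes))
    return ReadSet(sample_id=sample_id, reads=reads)


@pytest.fixture
def small_sample(rng):
    return supplement_complements(random_reads(rng, n_reads=12, max_len=25))


@pytest.fixture
def sample_pair(rng):
    a = supplement_complements(random_reads(rng, n_reads=40, max_len=60, min_len=30, sample_id="x"))
    b = supplement_complements(random_reads(rng, n_reads=40, max_len=60, min_len=30, sample_id="y"))
    return a, b
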