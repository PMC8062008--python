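import numpy as np
import pytest

from mosaicscan import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(17)


@pytest.fixture
def small_aln():
    return Alignment(
        ["s1", "s2", "s3"],
        ["ACGTACGTACGT", "ACGAACGAACGA", "ACGTACGAACGT"],
    )


def random_alignment(rng, n, L, with_gaps=False):
    """Uniform random alignment, optionally with sparse gaps."""
    mat = rng.integers(0, 4, size=(n, L))
    rows = []
    for i in range(n):
        chars = [("ACGT")[b] for b in mat[i]]
        if with_gaps:
            for j in np.flatnonzero(rng.random(L) < 0.05):
                chars[j] = "-"
        rows.append("".join(chars))
    return Alignment([f"r{i+1}" for i in range(n)], rows)


@pytest.fixture
def random_aln_factory(rng):
    return lambda n, L, with_gaps=False: random_alignment(rng, n, L, with_gaps)
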