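import numpy as np
import pytest

from itdtrack import ReadPair, synthetic_reference


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


def make_pair(read_id, seq1, seq2, q1=None, q2=None, q=37):
    """ReadPair with constant quality unless explicit arrays are given."""
    if q1 is None:
        q1 = np.full(len(seq1), q, np.uint8)
    if q2 is None:
        q2 = np.full(len(seq2), q, np.uint8)
    return ReadPair(read_id, seq1, seq2, np.asarray(q1, np.uint8), np.asarray(q2, np.uint8))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
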