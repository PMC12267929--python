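import numpy as np
import pytest

from superbarcode.seqio import Alignment

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_alignment(rows, ids=None, fragment_id="frag"):
    """Build an Alignment from equal-length strings."""
    ids = ids or [f"s{i}" for i in range(1, len(rows) + 1)]
    matrix = np.vstack(
        [np.frombuffer(r.upper().encode(), dtype=np.uint8) for r in rows]
    )
    return Alignment(fragment_id, ids, matrix)


def random_seq(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
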