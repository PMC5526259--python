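import numpy as np
import pytest

from epiallele import Locus, ReadVector


def make_locus(values, mask=None, sample_ids=None, chrom="chr1"):
    """Build a locus directly from a read matrix (rows = reads)."""
    values = np.asarray(values, dtype=np.uint8)
    n, d = values.shape
    if mask is None:
        mask = np.ones((n, d), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    if sample_ids is None:
        sample_ids = ["s1"] * n
    positions = 1 + 10 * np.arange(d)
    reads = [ReadVector(values[i] * mask[i], mask[i], sample_ids[i]) for i in range(n)]
    return Locus(chrom, 1, int(positions[-1]), positions, reads)


def reads_from_strings(patterns, counts):
    """Stack `counts[k]` copies of each binary pattern string."""
    rows = []
    for pat, c in zip(patterns, counts):
        row = np.array([int(ch) for ch in pat], dtype=np.uint8)
        rows.extend([row] * c)
    return np.stack(rows)


@pytest.fixture
def locus_factory():
    return make_locus
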