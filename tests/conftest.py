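import numpy as np
import pytest

from atacpost.core import GenomicInterval
from atacpost.peaks import ScoredPeak


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_peaks(rng, n, sample="s", **kw):
    return [
        ScoredPeak(iv, float(rng.uniform(0.1, 50)), sample)
        for iv in random_intervals(rng, n, **kw)
    ]
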