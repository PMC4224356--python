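import numpy as np
import pytest

from epirecomb.intervals import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def layout():
    return GenomeLayout([("chr1", 1_000_000), ("chr2", 1_000_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def iset(intervals, layout=None):
    """Shorthand: build an IntervalSet from (chrom, start, end[, score]) tuples."""
    out = []
    for t in intervals:
        if len(t) == 3:
            out.append(GenomicInterval(*t))
        else:
            out.append(GenomicInterval(t[0], t[1], t[2], score=t[3]))
    return IntervalSet(out, layout)


def random_intervals(rng, n, chroms=("chr1", "chr2"), clen=1_000_000, max_len=5_000):
    names = rng.choice(chroms, size=n)
    lengths = rng.integers(1, max_len, size=n)
    starts = rng.integers(0, clen - max_len, size=n)
    return IntervalSet(
        [GenomicInterval(str(c), int(s), int(s + l)) for c, s, l in zip(names, starts, lengths)]
    )
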