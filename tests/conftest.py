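import numpy as np
import pytest

from cobindclock.peak_io import Cistrome, GenomeLayout, GenomicPeak


@pytest.fixture
def layout():
    return GenomeLayout(("chr1", "chr2"), (1_000_000, 1_000_000))


def make_cistrome(label, summits, chrom="chr1", fe=None, half=150,
                  name_prefix=None):
    """Cistrome from summit positions; fe is a scalar, list or None."""
    prefix = name_prefix or label
    peaks = []
    for i, s in enumerate(summits):
        if fe is None:
            f = None
        elif np.isscalar(fe):
            f = float(fe)
        else:
            f = fe[i]
        peaks.append(GenomicPeak(chrom, max(0, s - half), s + half, s,
                                 f"{prefix}_{i}", f))
    return Cistrome(label, peaks)


def random_cistrome(rng, label, n, chroms=("chr1", "chr2"),
                    span=1_000_000, with_fe=False):
    summits = rng.integers(200, span - 200, size=n)
    chrom_pick = rng.integers(0, len(chroms), size=n)
    peaks = [
        GenomicPeak(chroms[c], int(s) - 150, int(s) + 150, int(s),
                    f"{label}_{i}",
                    float(rng.uniform(1, 50)) if with_fe else None)
        for i, (c, s) in enumerate(zip(chrom_pick, summits))
    ]
    return Cistrome(label, peaks)


def brute_force_nearest(query, ref, self_mode=False):
    """All-pairs nearest-summit oracle: (distances in query order, orphans)."""
    distances, orphans = [], 0
    for qp in query:
        ds = [abs(qp.summit - rp.summit) for rp in ref
              if rp.chrom == qp.chrom
              and not (self_mode and rp.name == qp.name)]
        if ds:
            distances.append(min(ds))
        else:
            orphans += 1
    return distances, orphans
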