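import numpy as np
import pytest

from promcoloc import GenomicInterval, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_peakset(rng, label, n=50, chrom_length=10_000, chroms=("chr1",),
                   max_width=400):
    """Random intervals on small chromosomes for oracle comparisons."""
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_length - 2))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, min(start + width, chrom_length),
                                   name=f"{label}_{i}"))
    return PeakSet(label, ivs)
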