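import numpy as np
import pytest

from hidra.fragio import Fragment, GenomicInterval, SampleManifest


@pytest.fixture
def manifest() -> SampleManifest:
    """Standard 5 DNA + 5 RNA replicate design."""
    return SampleManifest.default(5, 5)


@pytest.fixture
def small_manifest() -> SampleManifest:
    return SampleManifest.default(2, 2)


def make_fragment(chrom="chr1", start=100, end=300, barcode="ACGT", counts=None, n_samples=10):
    if counts is None:
        counts = np.ones(n_samples, dtype=np.int64)
    return Fragment(GenomicInterval(chrom, start, end), barcode, np.asarray(counts, dtype=np.int64))


@pytest.fixture
def make_frag():
    return make_fragment
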