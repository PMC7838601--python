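import numpy as np
import pytest

from dpcnv.profile import BinProfile


@pytest.fixture
def flat_profile():
    """120 bins of constant depth 50 on one chromosome."""
    n = 120
    return BinProfile(
        chrom=np.array(["chr1"] * n, dtype=object),
        start=np.arange(n) * 1000,
        width=1000,
        count=np.full(n, 50),
        gc=np.full(n, 0.45),
    )


def make_profile(counts, gc=None, width=1000, chrom="chr1"):
    counts = np.asarray(counts)
    n = len(counts)
    return BinProfile(
        chrom=np.array([chrom] * n, dtype=object),
        start=np.arange(n) * width,
        width=width,
        count=counts,
        gc=None if gc is None else np.asarray(gc, dtype=float),
    )
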