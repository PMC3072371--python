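import numpy as np
import pytest

from strainmap.types import GenotypePanel


def make_panel(calls, chrom=None, pos=None, snp_ids=None, strain_ids=None):
    """Small-panel constructor for tests; calls is (strains x snps)."""
    calls = np.asarray(calls, dtype=float)
    s, m = calls.shape
    if chrom is None:
        chrom = ["chr1"] * m
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if snp_ids is None:
        snp_ids = [f"s{j}" for j in range(m)]
    if strain_ids is None:
        strain_ids = [f"st{i}" for i in range(s)]
    return GenotypePanel(
        snp_ids=np.asarray(snp_ids, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * m, dtype=object),
        alt=np.asarray(["G"] * m, dtype=object),
        calls=calls,
        strain_ids=np.asarray(strain_ids, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
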