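import numpy as np
import pytest

from duogenie.sumstats_io import SumStatRecord


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.05,
    se=0.01,
    pval=1e-6,
    n=10_000,
) -> SumStatRecord:
    return SumStatRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
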