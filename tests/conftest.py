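import numpy as np
import pytest

from protmr.ld import LDBlock, LDCollection
from protmr.sumstats_io import SummaryStatSet, normal_p


def make_sumstats(
    trait_id,
    variant_ids,
    beta,
    se,
    chrom=None,
    pos=None,
    ea=None,
    oa=None,
    eaf=None,
    n=10_000,
    trait_kind="protein",
):
    """Hand-built SummaryStatSet for unit tests."""
    m = len(variant_ids)
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    return SummaryStatSet(
        trait_id=trait_id,
        trait_kind=trait_kind,
        variant_id=np.array(variant_ids, dtype=object),
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(m) * 1000 + 1,
                       dtype=np.int64),
        effect_allele=np.array(ea if ea is not None else ["A"] * m, dtype=object),
        other_allele=np.array(oa if oa is not None else ["G"] * m, dtype=object),
        eaf=np.asarray(eaf if eaf is not None else np.full(m, 0.3), dtype=float),
        beta=beta,
        se=se,
        pvalue=np.asarray(normal_p(beta / se)),
        n=np.full(m, n, dtype=np.int64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ld_r2_triplet():
    """Three variants with r²(v1,v2)=0.5 and r²(v·,v3)=0.05."""
    r12 = np.sqrt(0.5)
    r13 = np.sqrt(0.05)
    R = np.array([
        [1.0, r12, r13],
        [r12, 1.0, r13],
        [r13, r13, 1.0],
    ])
    block = LDBlock(["v1", "v2", "v3"], R)
    block.validate()
    return LDCollection([block])
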