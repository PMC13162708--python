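import numpy as np
import pytest

from conslift.chains import ChainAlignment, ChainBlock, ChainIndex


def make_identity_chain(seq="chr1", size=1000, q_name="tA.chr1", chain_id=1,
                        score=1000.0) -> ChainAlignment:
    c = ChainAlignment(score=score, t_name=seq, t_size=size, t_strand="+",
                       t_start=0, t_end=size, q_name=q_name, q_size=size,
                       q_strand="+", q_start=0, q_end=size, chain_id=chain_id,
                       blocks=[ChainBlock(size, 0, 0)])
    c.validate()
    return c


@pytest.fixture
def identity_index():
    return ChainIndex([make_identity_chain()])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
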