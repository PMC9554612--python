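import numpy as np
import pytest

from metaqtl.catalog import QTLRecord
from metaqtl.linkage import ConsensusMap, LinkageMap


@pytest.fixture
def simple_map():
    return LinkageMap(
        "m1",
        {"1A": [("A", 0.0), ("B", 10.0), ("C", 20.0), ("D", 30.0)]},
    )


@pytest.fixture
def simple_consensus(simple_map):
    return ConsensusMap(
        "consensus",
        dict(simple_map.entries),
        provenance={"1A": {m: ("m1",) for m, _ in simple_map.entries["1A"]}},
    )


@pytest.fixture
def scaled_consensus():
    """Same markers as simple_map but doubled distances."""
    return ConsensusMap(
        "consensus",
        {"1A": [("A", 0.0), ("B", 20.0), ("C", 40.0), ("D", 60.0)]},
        provenance={"1A": {m: ("m1",) for m in "ABCD"}},
    )


def make_record(qtl_id="q1", study="S1", chrom="1A", peak=5.0, ci=(2.0, 8.0),
                lod=4.0, pve=10.0, pop_type="RIL", pop_size=163,
                flanks=("A", "B")):
    return QTLRecord(
        qtl_id=qtl_id, study_id=study, population_type=pop_type,
        population_size=pop_size, chromosome=chrom,
        flank_lo=flanks[0], flank_hi=flanks[1],
        peak=peak, ci_lo=ci[0], ci_hi=ci[1], lod=lod, pve=pve,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
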