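import numpy as np
import pytest

from cnvpopscan import CohortCallset, SVRecord, SVType


def make_record(
    record_id="sv1",
    chrom="1",
    pos=1000,
    end=None,
    svtype=SVType.DEL,
    svlen=None,
    genotypes=(0, 1, 2),
):
    """Build a consistent SVRecord from minimal arguments."""
    svtype = SVType(svtype)
    if svtype is SVType.INS:
        end = pos
        svlen = svlen if svlen is not None else 100
    else:
        end = end if end is not None else pos + 99
        length = end - pos + 1
        svlen = svlen if svlen is not None else (-length if svtype is SVType.DEL else length)
    return SVRecord(
        record_id=record_id, chrom=chrom, pos=pos, end=end, svtype=svtype,
        svlen=svlen, genotypes=np.asarray(genotypes, dtype=np.int8),
    )


def make_callset(records, n_samples=None, pops=None):
    n = n_samples if n_samples is not None else len(records[0].genotypes)
    samples = [f"s{i}" for i in range(n)]
    cs = CohortCallset(samples=samples, records=list(records))
    if pops is not None:
        cs.pop_of = {s: pops[i] for i, s in enumerate(samples)}
    cs.sort_records()
    cs.validate()
    return cs


@pytest.fixture
def two_pop_callset():
    """6 samples (3 per population), 3 variants with known frequencies."""
    recs = [
        make_record("d1", pos=1000, end=1999, genotypes=[2, 2, 2, 0, 0, 0]),  # fixed diff
        make_record("d2", pos=5000, end=5999, genotypes=[0, 1, 1, 0, 1, 1]),  # equal freq
        make_record("i1", pos=9000, svtype=SVType.INS, genotypes=[0, 0, 1, 0, 0, 0]),
    ]
    return make_callset(recs, pops=["A", "A", "A", "B", "B", "B"])
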