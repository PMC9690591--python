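import itertools

import numpy as np
import pytest

from cnvpopscan import (
    MergeConfig,
    SVType,
    genotype_concordance,
    ins_similarity,
    merge_callset,
    reciprocal_overlap,
)
from cnvpopscan.model import CohortCallset

from conftest import make_callset, make_record


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        a = make_record("a", pos=100, end=199)
        b = make_record("b", pos=100, end=199)
        assert reciprocal_overlap(a, b) == 1.0

    def test_half_overlap(self):
        a = make_record("a", pos=100, end=199)
        b = make_record("b", pos=150, end=249)
        assert reciprocal_overlap(a, b) == pytest.approx(0.5)

    def test_disjoint_and_cross_chrom(self):
        a = make_record("a", pos=100, end=199)
        assert reciprocal_overlap(a, make_record("b", pos=300, end=399)) == 0.0
        assert reciprocal_overlap(a, make_record("b", chrom="2", pos=100, end=199)) == 0.0

    def test_asymmetric_sizes_take_min(self):
        big = make_record("a", pos=1, end=10_000)
        small = make_record("b", pos=1, end=100)
        assert reciprocal_overlap(big, small) == pytest.approx(100 / 10_000)

    def test_ins_input_redirected(self):
        a = make_record("a", svtype=SVType.INS)
        with pytest.raises(ValueError, match="ins_similarity"):
            reciprocal_overlap(a, make_record("b", pos=100, end=199))


class TestInsSimilarity:
    def test_same_pos_same_length(self):
        a = make_record("a", pos=500, svtype=SVType.INS, svlen=200)
        b = make_record("b", pos=500, svtype=SVType.INS, svlen=200)
        assert ins_similarity(a, b, window=100)

    def test_window_is_inclusive_bound(self):
        a = make_record("a", pos=500, svtype=SVType.INS, svlen=200)
        at = make_record("b", pos=600, svtype=SVType.INS, svlen=200)
        beyond = make_record("c", pos=601, svtype=SVType.INS, svlen=200)
        assert ins_similarity(a, at, window=100)
        assert not ins_similarity(a, beyond, window=100)

    def test_length_ratio_gate(self):
        a = make_record("a", pos=500, svtype=SVType.INS, svlen=89)
        b = make_record("b", pos=500, svtype=SVType.INS, svlen=100)
        assert not ins_similarity(a, b, window=100)  # 0.89 < 0.90
        c = make_record("c", pos=500, svtype=SVType.INS, svlen=90)
        assert ins_similarity(c, b, window=100)      # 0.90 >= 0.90

    def test_non_ins_rejected(self):
        with pytest.raises(ValueError):
            ins_similarity(make_record("a"), make_record("b", svtype=SVType.INS), 100)


class TestGenotypeConcordance:
    def test_identical_vectors(self):
        a = make_record("a", genotypes=[0, 1, 2] * 7)
        b = make_record("b", genotypes=[0, 1, 2] * 7)
        assert genotype_concordance(a, b) == 1.0

    def test_nineteen_of_twenty(self):
        g = [1] * 20
        h = [1] * 19 + [2]
        assert genotype_concordance(
            make_record("a", genotypes=g), make_record("b", genotypes=h)
        ) == pytest.approx(0.95)

    def test_missing_excluded_from_denominator(self):
        a = make_record("a", genotypes=[1, 1, -1, 1])
        b = make_record("b", genotypes=[1, -1, 1, 2])
        # jointly called: samples 0 and 3 -> 1 of 2 agree
        assert genotype_concordance(a, b) == pytest.approx(0.5)

    def test_all_missing_record_scores_zero(self):
        a = make_record("a", genotypes=[-1, -1, -1])
        b = make_record("b", genotypes=[0, 1, 2])
        assert genotype_concordance(a, b) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            genotype_concordance(
                make_record("a", genotypes=[0, 1]), make_record("b", genotypes=[0, 1, 2])
            )


class TestMergeCallset:
    def test_identical_records_collapse(self):
        recs = [
            make_record("a", pos=1000, end=1999, genotypes=[0, 1, 2]),
            make_record("b", pos=1000, end=1999, genotypes=[0, 1, 2]),
        ]
        merged, clusters = merge_callset(make_callset(recs))
        assert len(merged) == 1
        assert clusters[0].n_members == 2

    def test_del_at_60pct_overlap_merges(self):
        recs = [
            make_record("a", pos=1001, end=2000, genotypes=[0, 1, 2]),
            make_record("b", pos=1401, end=2400, genotypes=[0, 1, 2]),
        ]
        merged, _ = merge_callset(make_callset(recs))
        assert len(merged) == 1

    def test_dup_at_60pct_overlap_does_not_merge(self):
        recs = [
            make_record("a", pos=1001, end=2000, svtype=SVType.DUP, genotypes=[0, 1, 2]),
            make_record("b", pos=1401, end=2400, svtype=SVType.DUP, genotypes=[0, 1, 2]),
        ]
        merged, _ = merge_callset(make_callset(recs))
        assert len(merged) == 2

    def test_discordant_genotypes_block_merge(self):
        recs = [
            make_record("a", pos=1000, end=1999, genotypes=[0, 1, 2]),
            make_record("b", pos=1000, end=1999, genotypes=[2, 1, 0]),
        ]
        merged, _ = merge_callset(make_callset(recs))
        assert len(merged) == 2

    def test_representative_has_fewest_missing(self):
        recs = [
            make_record("a", pos=1000, end=1999, genotypes=[0, -1, 2]),
            make_record("b", pos=1000, end=1999, genotypes=[0, -1, -1]),
            make_record("c", pos=1001, end=2000, genotypes=[0, 1, 2]),
        ]
        merged, clusters = merge_callset(make_callset(recs))
        assert len(merged) == 1
        assert clusters[0].representative.record_id == "c"

    def test_cross_type_never_merges(self):
        recs = [
            make_record("a", pos=1000, end=1999, svtype=SVType.DEL, genotypes=[0, 1, 2]),
            make_record("b", pos=1000, end=1999, svtype=SVType.DUP, genotypes=[0, 1, 2]),
        ]
        merged, _ = merge_callset(make_callset(recs))
        assert len(merged) == 2


def _random_callset(rng, n_records, n_samples=6):
    recs = []
    for k in range(n_records):
        svtype = [SVType.DEL, SVType.DUP, SVType.INS][rng.integers(0, 3)]
        chrom = str(rng.integers(1, 3))
        g = rng.integers(-1, 3, n_samples)
        if svtype is SVType.INS:
            recs.append(make_record(f"r{k}", chrom=chrom, pos=int(rng.integers(1, 2000)),
                                    svtype=svtype, svlen=int(rng.integers(50, 200)),
                                    genotypes=g))
        else:
            pos = int(rng.integers(1, 2000))
            length = int(rng.integers(50, 1200))
            recs.append(make_record(f"r{k}", chrom=chrom, pos=pos, end=pos + length - 1,
                                    svtype=svtype, genotypes=g))
    return make_callset(recs, n_samples=n_samples)


def _brute_force_partition(callset, cfg):
    """Oracle: all-pairs edge enumeration + connected components."""
    from cnvpopscan.merge import _linked

    recs = callset.records
    n = len(recs)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = recs[i], recs[j]
        if a.chrom != b.chrom or a.svtype != b.svtype:
            continue
        if _linked(a, b, cfg):
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(frozenset(recs[u].record_id for u in comp))
    return set(comps)


class TestMergeProperties:
    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(42)
        cfg = MergeConfig()
        for _ in range(100):
            cs = _random_callset(rng, int(rng.integers(2, 31)))
            _, clusters = merge_callset(cs, cfg)
            got = {frozenset(m.record_id for m in c.members) for c in clusters}
            assert got == _brute_force_partition(cs, cfg)

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cs = _random_callset(rng, 25)
            once, _ = merge_callset(cs)
            twice, _ = merge_callset(once)
            assert [r.record_id for r in twice.records] == [r.record_id for r in once.records]

    def test_conservation(self):
        rng = np.random.default_rng(8)
        cs = _random_callset(rng, 30)
        merged, clusters = merge_callset(cs)
        assert sum(c.n_members for c in clusters) == len(cs)
        assert len(merged) == len(clusters) <= len(cs)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        cs = _random_callset(rng, 25)
        merged1, cl1 = merge_callset(cs)
        shuffled = CohortCallset(
            samples=cs.samples,
            records=[cs.records[i] for i in rng.permutation(len(cs.records))],
        )
        merged2, cl2 = merge_callset(shuffled)
        assert [r.record_id for r in merged1.records] == [r.record_id for r in merged2.records]
        p1 = {frozenset(m.record_id for m in c.members) for c in cl1}
        p2 = {frozenset(m.record_id for m in c.members) for c in cl2}
        assert p1 == p2
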