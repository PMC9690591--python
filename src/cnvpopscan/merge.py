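"""Group-level de-redundancy of SV calls.

Same-type records on the same chromosome are single-linkage clustered.
Two records are linked when their coordinates agree — 50% reciprocal
overlap for deletions, 90% for duplications, and for insertions a
breakpoint window plus a 90% length-ratio gate — AND their genotype
vectors are concordant in at least 95% of jointly called samples. One
representative per cluster survives: the member with the fewest missing
genotypes, ties broken by smallest (pos, end, record_id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CohortCallset, Genotype, MergeConfig, SVRecord, SVType

__all__ = ["reciprocal_overlap", "ins_similarity", "genotype_concordance",
           "merge_callset", "MergeCluster"]


@dataclass
class MergeCluster:
    representative: SVRecord
    members: list[SVRecord]

    @property
    def n_members(self) -> int:
        return len(self.members)


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """min(intersection/|a|, intersection/|b|) over 1-based inclusive intervals.

    Defined for DEL/DUP only; 0 when disjoint or on different chromosomes.
    """
    if a.svtype is SVType.INS or b.svtype is SVType.INS:
        raise ValueError("reciprocal_overlap is undefined for INS; use ins_similarity")
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.pos, b.pos) + 1
    if inter <= 0:
        return 0.0
    len_a = a.end - a.pos + 1
    len_b = b.end - b.pos + 1
    return min(inter / len_a, inter / len_b)


def ins_similarity(a: SVRecord, b: SVRecord, window: int, length_ratio_min: float = 0.90) -> bool:
    """Insertion equivalence: breakpoints within ``window`` bp and inserted
    lengths within the ratio gate (min/max >= ``length_ratio_min``)."""
    if a.svtype is not SVType.INS or b.svtype is not SVType.INS:
        raise ValueError("ins_similarity requires two INS records")
    if a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > window:
        return False
    la, lb = abs(a.svlen), abs(b.svlen)
    return min(la, lb) / max(la, lb) >= length_ratio_min


def genotype_concordance(a: SVRecord, b: SVRecord) -> float:
    """Fraction of jointly non-missing samples with identical genotype state.

    Returns 0 when no sample is called in both records — missingness never
    counts as agreement.
    """
    if a.genotypes.shape != b.genotypes.shape:
        raise ValueError("genotype vectors are not aligned to the same sample list")
    both = (a.genotypes != Genotype.MISSING) & (b.genotypes != Genotype.MISSING)
    n = int(both.sum())
    if n == 0:
        return 0.0
    return float((a.genotypes[both] == b.genotypes[both]).sum()) / n


def _linked(a: SVRecord, b: SVRecord, cfg: MergeConfig) -> bool:
    if a.svtype is SVType.INS:
        if not ins_similarity(a, b, cfg.ins_breakpoint_window, cfg.dupins_overlap):
            return False
    else:
        thr = cfg.del_overlap if a.svtype is SVType.DEL else cfg.dupins_overlap
        if reciprocal_overlap(a, b) < thr:
            return False
    return genotype_concordance(a, b) >= cfg.concordance_min


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _representative(members: list[SVRecord]) -> SVRecord:
    return min(members, key=lambda r: (r.n_missing(), r.pos, r.end, r.record_id))


def merge_callset(
    callset: CohortCallset, cfg: MergeConfig | None = None
) -> tuple[CohortCallset, list[MergeCluster]]:
    """Collapse redundant calls; returns (merged callset, clusters).

    Clustering is single-linkage within (chrom, svtype) over a sorted
    sweep: DEL/DUP pairs can only be linked while intervals intersect,
    INS pairs only within the breakpoint window, so each record is
    compared against a bounded neighbourhood. Output is independent of
    input record order.
    """
    cfg = cfg or MergeConfig()
    callset.validate()
    groups: dict[tuple[str, str], list[SVRecord]] = {}
    for rec in callset.records:
        groups.setdefault((rec.chrom, rec.svtype.value), []).append(rec)

    clusters: list[MergeCluster] = []
    for key in sorted(groups):
        recs = sorted(groups[key], key=SVRecord.sort_key)
        n = len(recs)
        uf = _UnionFind(n)
        is_ins = recs[0].svtype is SVType.INS
        # max interval end seen so far bounds how far back a link can reach
        for i in range(n):
            for j in range(i + 1, n):
                if is_ins:
                    if recs[j].pos - recs[i].pos > cfg.ins_breakpoint_window:
                        break
                else:
                    if recs[j].pos > recs[i].end:
                        break
                if _linked(recs[i], recs[j], cfg):
                    uf.union(i, j)
        by_root: dict[int, list[SVRecord]] = {}
        for i in range(n):
            by_root.setdefault(uf.find(i), []).append(recs[i])
        for root in sorted(by_root):
            members = by_root[root]
            clusters.append(MergeCluster(representative=_representative(members), members=members))

    merged = CohortCallset(
        samples=list(callset.samples),
        records=[c.representative for c in clusters],
        pop_of=dict(callset.pop_of),
    )
    merged.sort_records()
    clusters.sort(key=lambda c: c.representative.sort_key())
    return merged, clusters


def clusters_to_rows(clusters: list[MergeCluster]) -> list[dict]:
    """Tabular view of clusters for TSV export."""
    return [
        {
            "representative_id": c.representative.record_id,
            "member_ids": ",".join(m.record_id for m in c.members),
            "size": c.n_members,
        }
        for c in clusters
    ]
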