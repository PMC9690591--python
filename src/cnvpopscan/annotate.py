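"""Positional classification of CNVs against gene models.

Each variant receives exactly one of eleven classes, decided by a fixed
precedence order (first hit across all overlapping transcripts wins):

1. ``exonic``      — overlaps a CDS interval of a coding transcript;
2. ``splicing``    — overlaps the first/last ``splice_bp`` bases of an intron;
3. ``ncRNA``       — overlaps an exon of a non-coding transcript;
4. ``UTR3_UTR5``   — overlaps both a 5' and a 3' UTR (same or different
   transcripts); else ``UTR5`` / ``UTR3``;
5. ``intronic``    — overlaps an intron;
6. ``upstream_downstream`` — within ``upstream_bp`` of a TSS and of a TES
   (strand-aware, possibly different genes); else ``upstream`` / ``downstream``;
7. ``intergenic``  — none of the above.

The vocabulary and precedence follow the ANNOVAR convention for
gene-based annotation; the upstream/downstream window (1000 bp) and the
splice window (2 bp) are configurable.
"""

from __future__ import annotations

import enum
from collections import Counter

from .model import GeneModel, SVRecord, SVType

__all__ = ["AnnotationClass", "classify_variant", "classify_callset", "summarize_annotation"]


class AnnotationClass(str, enum.Enum):
    EXONIC = "exonic"
    SPLICING = "splicing"
    NCRNA = "ncRNA"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    UTR3_UTR5 = "UTR3_UTR5"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    UPSTREAM_DOWNSTREAM = "upstream_downstream"
    INTERGENIC = "intergenic"


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 <= e2 and s2 <= e1


def classify_variant(
    record: SVRecord,
    genes: list[GeneModel],
    upstream_bp: int = 1000,
    splice_bp: int = 2,
) -> AnnotationClass:
    """Classify one variant; the variant interval is [pos, end]
    (a single anchor base for insertions)."""
    vs, ve = record.pos, record.end if record.svtype is not SVType.INS else record.pos
    hit_cds = hit_splice = hit_ncrna = hit_u5 = hit_u3 = hit_intron = False
    hit_up = hit_down = False
    for g in genes:
        if g.chrom != record.chrom:
            continue
        near = _overlaps(vs, ve, g.start - upstream_bp, g.end + upstream_bp)
        if not near:
            continue
        if g.biotype == "coding":
            if any(_overlaps(vs, ve, s, e) for s, e in g.cds):
                hit_cds = True
            if any(_overlaps(vs, ve, s, e) for s, e in g.utr5):
                hit_u5 = True
            if any(_overlaps(vs, ve, s, e) for s, e in g.utr3):
                hit_u3 = True
        else:
            if any(_overlaps(vs, ve, s, e) for s, e in g.exons):
                hit_ncrna = True
        for is_, ie in g.introns():
            if _overlaps(vs, ve, is_, ie):
                hit_intron = True
                if splice_bp > 0 and (
                    _overlaps(vs, ve, is_, min(ie, is_ + splice_bp - 1))
                    or _overlaps(vs, ve, max(is_, ie - splice_bp + 1), ie)
                ):
                    hit_splice = True
        # strand-aware promoter-side / tail-side windows
        if g.strand == "+":
            up_iv = (g.start - upstream_bp, g.start - 1)
            down_iv = (g.end + 1, g.end + upstream_bp)
        else:
            up_iv = (g.end + 1, g.end + upstream_bp)
            down_iv = (g.start - upstream_bp, g.start - 1)
        if _overlaps(vs, ve, *up_iv):
            hit_up = True
        if _overlaps(vs, ve, *down_iv):
            hit_down = True
    if hit_cds:
        return AnnotationClass.EXONIC
    if hit_splice:
        return AnnotationClass.SPLICING
    if hit_ncrna:
        return AnnotationClass.NCRNA
    if hit_u5 and hit_u3:
        return AnnotationClass.UTR3_UTR5
    if hit_u5:
        return AnnotationClass.UTR5
    if hit_u3:
        return AnnotationClass.UTR3
    if hit_intron:
        return AnnotationClass.INTRONIC
    if hit_up and hit_down:
        return AnnotationClass.UPSTREAM_DOWNSTREAM
    if hit_up:
        return AnnotationClass.UPSTREAM
    if hit_down:
        return AnnotationClass.DOWNSTREAM
    return AnnotationClass.INTERGENIC


def classify_callset(
    records: list[SVRecord],
    genes: list[GeneModel],
    upstream_bp: int = 1000,
    splice_bp: int = 2,
) -> list[AnnotationClass]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        classify_variant(r, by_chrom.get(r.chrom, []), upstream_bp, splice_bp)
        for r in records
    ]


def summarize_annotation(classes: list[AnnotationClass]) -> dict[str, int]:
    """Count table over all eleven classes; counts sum to the input size."""
    c = Counter(classes)
    return {cls.value: c.get(cls, 0) for cls in AnnotationClass}
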