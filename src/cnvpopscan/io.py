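"""Readers and writers: SV VCF 4.2 dialect, GFF3 gene models, popmap TSV.

The VCF dialect is the one emitted by short-read SV genotypers: symbolic
ALT alleles, ``SVTYPE``/``SVLEN`` (and ``END`` for DEL/DUP) in INFO, ``GT``
first in FORMAT. Records are biallelic; multiallelic lines are rejected
rather than split.
"""

from __future__ import annotations

import warnings

import gffutils
import numpy as np
import pandas as pd
import pysam

from .model import CohortCallset, GeneModel, Genotype, SVRecord, SVType

__all__ = ["read_sv_vcf", "write_sv_vcf", "read_gff3", "read_popmap", "write_popmap"]


class VCFParseError(ValueError):
    """A malformed record, reported with its 1-based line number."""


def _decode_gt(gt: tuple) -> int:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return Genotype.MISSING.value
    if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
        raise ValueError(f"unsupported GT {gt!r}")
    return alleles[0] + alleles[1]


def _scalar(value) -> int:
    if isinstance(value, (tuple, list)):
        value = value[0]
    return int(value)


def read_sv_vcf(path: str) -> CohortCallset:
    """Parse an SV VCF into a :class:`CohortCallset` (no population labels).

    Genotype tokens map onto four states: ``0/0``→hom_ref, ``0/1``/``1/0``
    (phased or not)→het, ``1/1``→hom_alt, ``./.``/``.``→missing. Records
    are returned sorted by (chrom, pos, end, svtype, record_id).
    """
    with open(path, "rb") as fh:
        n_header = 0
        for line in fh:
            if not line.startswith(b"#"):
                break
            n_header += 1
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        records: list[SVRecord] = []
        for idx, rec in enumerate(vf.fetch(), start=1):
            line_no = n_header + idx
            if rec.alts is None or len(rec.alts) != 1:
                raise VCFParseError(
                    f"line {line_no}: multiallelic ALT {rec.alts!r} not supported; "
                    "split or drop the record"
                )
            info = rec.info
            if "SVTYPE" not in info:
                raise VCFParseError(f"line {line_no}: missing INFO/SVTYPE")
            svtype_raw = str(info["SVTYPE"])
            try:
                svtype = SVType(svtype_raw)
            except ValueError:
                raise VCFParseError(
                    f"line {line_no}: unknown SVTYPE {svtype_raw!r} (expected DEL/DUP/INS)"
                ) from None
            if "SVLEN" not in info:
                raise VCFParseError(f"line {line_no}: missing INFO/SVLEN")
            svlen = _scalar(info["SVLEN"])
            pos = rec.pos
            # END is derived from SVLEN: htslib normalizes INFO/END for
            # symbolic SVs, so SVLEN is the authoritative size field
            end = pos if svtype is SVType.INS else pos + abs(svlen) - 1
            gts = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gts[i] = _decode_gt(rec.samples[s].get("GT", (None, None)))
            rid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{pos}_{svtype.value}"
            try:
                records.append(
                    SVRecord(
                        record_id=rid, chrom=rec.chrom, pos=pos, end=end,
                        svtype=svtype, svlen=svlen, genotypes=gts,
                    )
                )
            except ValueError as exc:
                raise VCFParseError(f"line {line_no}: {exc}") from None
    cs = CohortCallset(samples=samples, records=records)
    cs.sort_records()
    cs.validate()
    return cs


_GT_OUT = {
    Genotype.HOM_REF.value: (0, 0),
    Genotype.HET.value: (0, 1),
    Genotype.HOM_ALT.value: (1, 1),
    Genotype.MISSING.value: (None, None),
}


def write_sv_vcf(callset: CohortCallset, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a callset as VCF 4.2; round-trips through :func:`read_sv_vcf`."""
    callset.validate()
    header = pysam.VariantHeader()
    lengths: dict[str, int] = dict(contig_lengths or {})
    for rec in callset.records:
        lengths[rec.chrom] = max(lengths.get(rec.chrom, 0), rec.end + 1)
    for chrom in sorted(lengths):
        header.contigs.add(chrom, length=lengths[chrom])
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in callset.samples:
        header.add_sample(s)
    ordered = sorted(callset.records, key=SVRecord.sort_key)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in ordered:
            vr = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.end,
                alleles=("N", f"<{rec.svtype.value}>"),
                id=rec.record_id,
            )
            vr.info["SVTYPE"] = rec.svtype.value
            vr.info["SVLEN"] = rec.svlen
            for i, s in enumerate(callset.samples):
                vr.samples[s]["GT"] = _GT_OUT[int(rec.genotypes[i])]
                vr.samples[s].phased = False
            out.write(vr)


_TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "ncRNA", "lnc_RNA", "miRNA", "snoRNA", "snRNA",
    "rRNA", "tRNA", "pseudogenic_transcript",
}


def read_gff3(path: str) -> list[GeneModel]:
    """Load gene models from GFF3, one :class:`GeneModel` per transcript.

    Transcripts without CDS children are flagged ``biotype="ncRNA"``.
    A ``Parent`` attribute pointing at an undefined feature is an error.
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    ids = {f.id for f in db.all_features()}
    for f in db.all_features():
        for parent in f.attributes.get("Parent", []):
            if parent not in ids:
                raise ValueError(
                    f"feature {f.id!r} references undefined Parent {parent!r}"
                )
    models: list[GeneModel] = []
    for tr in db.all_features():
        if tr.featuretype not in _TRANSCRIPT_TYPES:
            continue
        parents = tr.attributes.get("Parent", [tr.id])
        gene_id = parents[0]
        exons = [(c.start, c.end) for c in db.children(tr, featuretype="exon")]
        if not exons:
            continue
        cds = [(c.start, c.end) for c in db.children(tr, featuretype="CDS")]
        utr5 = [(c.start, c.end) for c in db.children(tr, featuretype="five_prime_UTR")]
        utr3 = [(c.start, c.end) for c in db.children(tr, featuretype="three_prime_UTR")]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tr.id,
                chrom=tr.seqid,
                strand=tr.strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
                biotype="coding" if cds else "ncRNA",
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.end, m.transcript_id))
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    """Emit gene models as GFF3 (gene → transcript → exon/CDS/UTR)."""
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, trs in sorted(by_gene.items(), key=lambda kv: (kv[1][0].chrom, kv[1][0].start)):
            g_start = min(t.start for t in trs)
            g_end = max(t.end for t in trs)
            chrom, strand = trs[0].chrom, trs[0].strand
            fh.write(f"{chrom}\tcnvpopscan\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n")
            for t in trs:
                ftype = "mRNA" if t.biotype == "coding" else "ncRNA"
                fh.write(
                    f"{chrom}\tcnvpopscan\t{ftype}\t{t.start}\t{t.end}\t.\t{strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene_id}\n"
                )
                parts = (
                    [("exon", iv) for iv in t.exons]
                    + [("CDS", iv) for iv in t.cds]
                    + [("five_prime_UTR", iv) for iv in t.utr5]
                    + [("three_prime_UTR", iv) for iv in t.utr3]
                )
                for k, (ftype2, (s, e)) in enumerate(parts, start=1):
                    fh.write(
                        f"{chrom}\tcnvpopscan\t{ftype2}\t{s}\t{e}\t.\t{strand}\t"
                        f"{'0' if ftype2 == 'CDS' else '.'}\t"
                        f"ID={t.transcript_id}.{ftype2}.{k};Parent={t.transcript_id}\n"
                    )


def read_popmap(path: str, callset: CohortCallset) -> CohortCallset:
    """Attach population labels from a two-column TSV (sample_id, population).

    Every VCF sample must appear in the map; extra mapped samples are
    accepted with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    mapping = dict(zip(df["sample"], df["population"]))
    missing = [s for s in callset.samples if s not in mapping]
    if missing:
        raise ValueError(f"popmap {path}: samples missing from map: {missing}")
    extra = sorted(set(mapping) - set(callset.samples))
    if extra:
        warnings.warn(f"popmap {path}: {len(extra)} mapped sample(s) not in the VCF: {extra}")
    callset.pop_of = {s: mapping[s] for s in callset.samples}
    callset.validate()
    return callset


def write_popmap(callset: CohortCallset, path: str) -> None:
    with open(path, "w") as fh:
        for s in callset.samples:
            fh.write(f"{s}\t{callset.pop_of[s]}\n")
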