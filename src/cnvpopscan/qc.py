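"""Site-level quality control.

Four gates, applied to every record of the merged callset:

* event size: ``|SVLEN| <= 10 Mb``;
* excess heterozygosity: one-sided exact Hardy-Weinberg tail
  ``P(het count >= observed)`` under the conditional (Levene/Haldane)
  distribution of heterozygote counts given the allele counts, required
  to be ``>= 0.05`` — removes sites whose heterozygote excess betrays
  collapsed paralogs or systematic genotyping error;
* call rate: fraction of missing genotypes ``<= 0.2``;
* polymorphism: minor allele frequency strictly ``> 0`` over non-missing
  genotypes.

The exact test is computed by the numerically stable ratio recurrence
over admissible heterozygote counts (they share the parity of the minor
allele count), not by naive factorials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CohortCallset, Genotype, QCConfig, SVRecord

__all__ = ["SiteCounts", "site_counts", "exc_het_pvalue", "f_missing", "maf", "apply_qc"]


@dataclass(frozen=True)
class SiteCounts:
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing) < 0:
            raise ValueError("negative genotype count")

    @property
    def n_genotyped(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_total(self) -> int:
        return self.n_genotyped + self.n_missing


def site_counts(record: SVRecord) -> SiteCounts:
    g = record.genotypes
    return SiteCounts(
        n_hom_ref=int((g == Genotype.HOM_REF).sum()),
        n_het=int((g == Genotype.HET).sum()),
        n_hom_alt=int((g == Genotype.HOM_ALT).sum()),
        n_missing=int((g == Genotype.MISSING).sum()),
    )


def exc_het_pvalue(counts: SiteCounts) -> float:
    """Exact one-sided excess-heterozygosity p-value, P(het >= observed).

    Conditional on the observed allele counts, the heterozygote count h
    ranges over {r mod 2, r mod 2 + 2, ..., r} with r the minor allele
    count, with P(h) proportional to 2^h / (n_AA! h! n_BB!). Monomorphic
    sites are degenerate (single configuration) and return 1.0.
    """
    n = counts.n_genotyped
    if n == 0:
        raise ValueError("exc_het_pvalue requires at least one genotyped sample")
    na = counts.n_het + 2 * counts.n_hom_alt  # alt allele count
    nb = 2 * n - na
    r = min(na, nb)
    if r == 0:
        return 1.0
    obs = counts.n_het
    # unnormalized probabilities, descending from h_max = r via the ratio
    # P(h-2)/P(h) = h(h-1) / (4 (n_AA+1)(n_BB+1))
    h = r
    u = 1.0
    total = u
    tail = u if h >= obs else 0.0
    while h >= 2:
        # homozygote class sizes at het count h
        n_hom_a = (na - h) // 2
        n_hom_b = (nb - h) // 2
        u *= h * (h - 1) / (4.0 * (n_hom_a + 1) * (n_hom_b + 1))
        h -= 2
        total += u
        if h >= obs:
            tail += u
    return min(1.0, tail / total)


def f_missing(counts: SiteCounts) -> float:
    """Fraction of the cohort with a missing genotype."""
    if counts.n_total == 0:
        raise ValueError("empty cohort")
    return counts.n_missing / counts.n_total


def maf(counts: SiteCounts) -> float:
    """Minor allele frequency over non-missing genotypes."""
    n = counts.n_genotyped
    if n == 0:
        raise ValueError("maf requires at least one genotyped sample")
    p = (2 * counts.n_hom_alt + counts.n_het) / (2 * n)
    return min(p, 1.0 - p)


def apply_qc(
    callset: CohortCallset, cfg: QCConfig | None = None
) -> tuple[CohortCallset, list[dict]]:
    """Pure selection: keep records passing all four gates.

    The report lists, for every removed record, every rule it failed
    (``svlen``, ``exchet``, ``missing``, ``maf``). Records with zero
    genotyped samples fail ``missing`` (and ``maf``/``exchet`` are
    undefined, reported as failed).
    """
    cfg = cfg or QCConfig()
    callset.validate()
    kept: list[SVRecord] = []
    report: list[dict] = []
    for rec in callset.records:
        c = site_counts(rec)
        failed: list[str] = []
        if abs(rec.svlen) > cfg.max_abs_svlen:
            failed.append("svlen")
        if c.n_genotyped == 0:
            failed.extend(["missing", "exchet", "maf"])
        else:
            if exc_het_pvalue(c) < cfg.min_exchet_p:
                failed.append("exchet")
            if f_missing(c) > cfg.max_f_missing:
                failed.append("missing")
            if not (maf(c) > cfg.min_maf):
                failed.append("maf")
        if failed:
            report.append({"record_id": rec.record_id, "failed": failed})
        else:
            kept.append(rec)
    out = CohortCallset(samples=list(callset.samples), records=kept, pop_of=dict(callset.pop_of))
    return out, report
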