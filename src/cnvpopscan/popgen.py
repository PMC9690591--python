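"""Allele frequencies, frequency spectra, per-variant Fst and the
top-percentile selection scan.

Differentiation between two populations is measured per variant with
Wright's fixation index in its heterozygosity form,

    Fst = (Ht - Hs) / Ht,

where ``Ht = 2 p̄ (1 - p̄)`` is the expected heterozygosity of the pooled
population at the unweighted mean frequency ``p̄ = (p_a + p_b)/2`` and
``Hs`` is the unweighted mean of the two subpopulation expected
heterozygosities ``2 p (1 - p)``. No sample-size correction is applied;
per-variant values are therefore upward-biased at small n, which does not
affect a rank-based top-percentile scan. Monomorphic pooled sites
(``Ht = 0``) carry no differentiation signal and are assigned Fst 0.
Sites on configured sex chromosomes are omitted from the scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_SEX_CHROMOSOMES,
    CohortCallset,
    Genotype,
    SpectrumConfig,
    SVRecord,
)

__all__ = [
    "FstResult",
    "allele_freq",
    "fst_per_variant",
    "select_top_fraction",
    "frequency_spectrum",
    "callset_comparison",
    "callset_summary",
    "fst_from_frequencies",
]


@dataclass
class FstResult:
    record_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    p_a: float
    p_b: float
    ht: float
    hs: float
    fst: float
    selected: bool = False


def allele_freq(record: SVRecord, sample_idx: np.ndarray | None = None) -> float | None:
    """Alt-allele frequency over non-missing genotypes in the subset.

    Returns None (undefined) when every genotype in the subset is missing;
    callers exclude such records from dependent statistics.
    """
    g = record.genotypes if sample_idx is None else record.genotypes[sample_idx]
    called = g[g != Genotype.MISSING]
    if called.size == 0:
        return None
    return float(called.sum()) / (2 * called.size)


def fst_from_frequencies(p_a: float, p_b: float) -> tuple[float, float, float]:
    """(Ht, Hs, Fst) from the two subpopulation alt-allele frequencies."""
    p_bar = (p_a + p_b) / 2.0
    ht = 2.0 * p_bar * (1.0 - p_bar)
    hs = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    fst = (ht - hs) / ht if ht > 0 else 0.0
    return ht, hs, float(min(max(fst, 0.0), 1.0))


def fst_per_variant(
    callset: CohortCallset,
    pop_a: str,
    pop_b: str,
    sex_chromosomes: frozenset[str] | set[str] = DEFAULT_SEX_CHROMOSOMES,
) -> list[FstResult]:
    """Per-variant Fst between two populations over autosomal records.

    Records on chromosomes in ``sex_chromosomes`` are omitted, as are
    records where either population has no called genotype.
    """
    idx_a = callset.sample_indices(pop_a)
    idx_b = callset.sample_indices(pop_b)
    out: list[FstResult] = []
    for rec in callset.records:
        if rec.chrom in sex_chromosomes:
            continue
        p_a = allele_freq(rec, idx_a)
        p_b = allele_freq(rec, idx_b)
        if p_a is None or p_b is None:
            continue
        ht, hs, fst = fst_from_frequencies(p_a, p_b)
        out.append(
            FstResult(
                record_id=rec.record_id, chrom=rec.chrom, pos=rec.pos, end=rec.end,
                svtype=rec.svtype.value, p_a=p_a, p_b=p_b, ht=ht, hs=hs, fst=fst,
            )
        )
    return out


def select_top_fraction(
    results: list[FstResult], fraction: float = 0.01
) -> tuple[float, list[FstResult]]:
    """Flag the top ``fraction`` of results by Fst; returns (threshold, selected).

    k = ceil(fraction * N); ranking by (Fst descending, record_id
    ascending); the threshold is the Fst of the k-th ranked result.
    Mutates the ``selected`` flag in place on all results.
    """
    if not results:
        raise ValueError("no Fst results to rank")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(results))
    ranked = sorted(results, key=lambda r: (-r.fst, r.record_id))
    for r in results:
        r.selected = False
    for r in ranked[:k]:
        r.selected = True
    return ranked[k - 1].fst, ranked[:k]


def frequency_spectrum(
    callset: CohortCallset, pop: str, cfg: SpectrumConfig | None = None
) -> pd.DataFrame:
    """Counts of variants per (svtype, frequency bin) in one population.

    Bins are right-closed: ((k-1)/n, k/n] for k = 1..n; variants at
    frequency 0 in the population (or with no called genotype there) are
    excluded. The returned frame has one row per bin with per-type columns
    and an ``all`` column.
    """
    cfg = cfg or SpectrumConfig()
    idx = callset.sample_indices(pop)
    nb = cfg.n_bins
    types = ["DEL", "DUP", "INS"]
    counts = {t: np.zeros(nb, dtype=int) for t in types}
    for rec in callset.records:
        p = allele_freq(rec, idx)
        if p is None or p <= 0:
            continue
        b = min(nb, int(math.ceil(p * nb)))  # right-closed edges
        counts[rec.svtype.value][b - 1] += 1
    edges = [((k - 1) / nb, k / nb) for k in range(1, nb + 1)]
    df = pd.DataFrame(
        {
            "bin": [f"({lo:g},{hi:g}]" for lo, hi in edges],
            **{t: counts[t] for t in types},
        }
    )
    df["all"] = df[types].sum(axis=1)
    if not cfg.by_type:
        df = df[["bin", "all"]]
    return df


def callset_comparison(
    callset: CohortCallset, pop_a: str, pop_b: str
) -> tuple[int, int, int]:
    """(n_shared, n_unique_a, n_unique_b) by frequency-based presence.

    A variant is present in a population iff its alt-allele frequency
    there is > 0. Variants absent from both populations are not counted.
    """
    idx_a = callset.sample_indices(pop_a)
    idx_b = callset.sample_indices(pop_b)
    shared = ua = ub = 0
    for rec in callset.records:
        p_a = allele_freq(rec, idx_a)
        p_b = allele_freq(rec, idx_b)
        in_a = p_a is not None and p_a > 0
        in_b = p_b is not None and p_b > 0
        if in_a and in_b:
            shared += 1
        elif in_a:
            ua += 1
        elif in_b:
            ub += 1
    return shared, ua, ub


def callset_summary(callset: CohortCallset, pop: str | None = None) -> dict:
    """Per-type counts and length statistics, Table-1 style.

    With ``pop`` given, only variants present there (frequency > 0) are
    counted; with ``pop=None`` every record counts. Lengths are |svlen|;
    the mean is additionally rounded to the nearest bp for display.
    """
    idx = callset.sample_indices(pop) if pop is not None else None
    per_type = {"DEL": 0, "DUP": 0, "INS": 0}
    lengths: list[int] = []
    len_by_type = {"DEL": 0, "DUP": 0, "INS": 0}
    for rec in callset.records:
        if idx is not None:
            p = allele_freq(rec, idx)
            if p is None or p <= 0:
                continue
        per_type[rec.svtype.value] += 1
        lengths.append(rec.length)
        len_by_type[rec.svtype.value] += rec.length
    total = sum(per_type.values())
    arr = np.asarray(lengths)
    return {
        "population": pop if pop is not None else "all",
        "n_total": total,
        "n_by_type": per_type,
        "total_length": int(arr.sum()) if total else 0,
        "length_by_type": len_by_type,
        "mean_length": float(arr.mean()) if total else None,
        "mean_length_bp": int(round(arr.mean())) if total else None,
        "median_length": float(np.median(arr)) if total else None,
    }
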