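"""Synthetic two-population CNV cohorts and gene models.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline runs without any external download:

* Two diploid populations (defaults 45 + 19 samples). Per variant, an
  ancestral alt-allele frequency ``p ~ Uniform(0.05, 0.95)`` and
  population frequencies drawn independently from the Balding-Nichols
  beta distribution ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with differentiation
  parameter ``F``; for ``F = 0`` the frequencies collapse to ``p``
  exactly. Genotypes are ``Binomial(2, p_pop)`` per sample, i.e.
  Hardy-Weinberg within populations, variants independent.
* DEL/DUP/INS variants with log-uniform lengths (50 bp - 100 kb for
  DEL/DUP, 50 bp - 1 kb for INS) placed uniformly on a synthetic genome
  of named autosomes.
* A ``dup_rate`` fraction of variants re-emitted as jittered
  near-duplicates (coordinates perturbed, jitter clamped so the pair
  stays above the default merge gates; genotypes copied, missingness
  redrawn) to exercise the de-redundancy stage.
* Per-genotype missingness at rate ``p_missing``.

A truth table records the drawn frequencies and duplicate-of links.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CohortCallset, GeneModel, SVRecord, SVType

__all__ = ["SimulationConfig", "simulate_callset", "simulate_gene_models"]

_DEFAULT_GENOME = [(str(i), 20_000_000) for i in range(1, 19)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-population cohort generator."""

    n_variants: int = 2000
    n_pop_a: int = 45
    n_pop_b: int = 19
    pop_a: str = "WBP"
    pop_b: str = "AWB"
    fst_param: float = 0.2
    type_mix: tuple[float, float, float] = (0.70, 0.03, 0.27)  # DEL, DUP, INS
    len_range_deldup: tuple[int, int] = (50, 100_000)
    len_range_ins: tuple[int, int] = (50, 1_000)
    genome: list[tuple[str, int]] = field(default_factory=lambda: list(_DEFAULT_GENOME))
    p_missing: float = 0.02
    dup_rate: float = 0.10
    jitter_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1 or self.n_pop_a < 1 or self.n_pop_b < 1:
            raise ValueError("n_variants and population sizes must be >= 1")
        if not (0 <= self.fst_param < 1):
            raise ValueError("fst_param must be in [0, 1)")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or min(self.type_mix) < 0:
            raise ValueError("type_mix must be non-negative and sum to 1")
        for rate in (self.p_missing, self.dup_rate):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")


def _loguniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _draw_pop_freqs(rng: np.random.Generator, p: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray]:
    if f == 0:
        return p.copy(), p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return rng.beta(a, b), rng.beta(a, b)


def _apply_missing(rng: np.random.Generator, g: np.ndarray, rate: float) -> np.ndarray:
    out = g.astype(np.int8).copy()
    if rate > 0:
        out[rng.random(g.shape) < rate] = -1
    return out


def _max_jitter(svtype: SVType, length: int, jitter_bp: int) -> int:
    # keep the jittered pair above the default merge gates by construction:
    # reciprocal overlap >= t needs jitter <= L(1-t)/(2(1+t)) per endpoint
    if svtype is SVType.DEL:
        bound = length // 6          # t = 0.5
    elif svtype is SVType.DUP:
        bound = length // 38         # t = 0.9
    else:
        bound = 100                  # INS breakpoint window
    return max(0, min(jitter_bp, bound))


def simulate_callset(cfg: SimulationConfig) -> tuple[CohortCallset, pd.DataFrame]:
    """Generate a cohort callset plus its truth table.

    The truth table has one row per emitted record: record_id, svtype,
    ancestral ``p``, population frequencies ``p_a``/``p_b``, and
    ``duplicate_of`` (empty for originals).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"{cfg.pop_a}_{i + 1:03d}" for i in range(cfg.n_pop_a)] + [
        f"{cfg.pop_b}_{i + 1:03d}" for i in range(cfg.n_pop_b)
    ]
    pop_of = {s: (cfg.pop_a if i < cfg.n_pop_a else cfg.pop_b) for i, s in enumerate(samples)}

    p_anc = rng.uniform(0.05, 0.95, cfg.n_variants)
    p_a, p_b = _draw_pop_freqs(rng, p_anc, cfg.fst_param)
    type_order = (SVType.DEL, SVType.DUP, SVType.INS)
    types = rng.choice(3, size=cfg.n_variants, p=list(cfg.type_mix))
    chrom_names = [c for c, _ in cfg.genome]
    chrom_lengths = {c: l for c, l in cfg.genome}
    chrom_idx = rng.integers(0, len(chrom_names), cfg.n_variants)

    records: list[SVRecord] = []
    truth_rows: list[dict] = []
    for k in range(cfg.n_variants):
        svtype = type_order[types[k]]
        chrom = chrom_names[chrom_idx[k]]
        clen = chrom_lengths[chrom]
        if svtype is SVType.INS:
            length = _loguniform_int(rng, *cfg.len_range_ins)
            pos = int(rng.integers(1, clen))
            end = pos
            svlen = length
        else:
            length = min(_loguniform_int(rng, *cfg.len_range_deldup), clen - 1)
            pos = int(rng.integers(1, clen - length + 1))
            end = pos + length - 1
            svlen = -length if svtype is SVType.DEL else length
        g_true = rng.binomial(
            2, np.concatenate([np.full(cfg.n_pop_a, p_a[k]), np.full(cfg.n_pop_b, p_b[k])])
        )
        rid = f"sv{k + 1:06d}"
        records.append(
            SVRecord(
                record_id=rid, chrom=chrom, pos=pos, end=end, svtype=svtype,
                svlen=svlen, genotypes=_apply_missing(rng, g_true, cfg.p_missing),
            )
        )
        truth_rows.append(
            {"record_id": rid, "svtype": svtype.value, "p_anc": p_anc[k],
             "p_a": p_a[k], "p_b": p_b[k], "duplicate_of": ""}
        )
        if rng.random() < cfg.dup_rate:
            jmax = _max_jitter(svtype, length, cfg.jitter_bp)
            if svtype is SVType.INS:
                dpos = int(np.clip(pos + rng.integers(-jmax, jmax + 1), 1, clen))
                dend, dsvlen = dpos, svlen
            else:
                d1 = int(rng.integers(-jmax, jmax + 1))
                d2 = int(rng.integers(-jmax, jmax + 1))
                dpos = max(1, pos + d1)
                dend = min(clen, max(dpos, end + d2))
                dlen = dend - dpos + 1
                dsvlen = -dlen if svtype is SVType.DEL else dlen
            drid = f"{rid}_dup"
            records.append(
                SVRecord(
                    record_id=drid, chrom=chrom, pos=dpos, end=dend, svtype=svtype,
                    svlen=dsvlen, genotypes=_apply_missing(rng, g_true, cfg.p_missing),
                )
            )
            truth_rows.append(
                {"record_id": drid, "svtype": svtype.value, "p_anc": p_anc[k],
                 "p_a": p_a[k], "p_b": p_b[k], "duplicate_of": rid}
            )

    callset = CohortCallset(samples=samples, records=records, pop_of=pop_of)
    callset.sort_records()
    callset.validate()
    return callset, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# gene models


def _planted_gene_models(chrom: str) -> tuple[list[GeneModel], list[dict]]:
    """Hand-placed genes guaranteeing one coordinate per annotation class."""
    gene_a = GeneModel(
        gene_id="geneA", transcript_id="geneA.t1", chrom=chrom, strand="+",
        exons=[(100_000, 100_199), (101_000, 101_399)],
        cds=[(100_100, 100_199), (101_000, 101_299)],
        utr5=[(100_000, 100_099)], utr3=[(101_300, 101_399)],
    )
    gene_b = GeneModel(
        gene_id="geneB", transcript_id="geneB.t1", chrom=chrom, strand="+",
        exons=[(102_000, 102_199), (102_800, 103_199)],
        cds=[(102_100, 102_199), (102_800, 103_099)],
        utr5=[(102_000, 102_099)], utr3=[(103_100, 103_199)],
    )
    gene_c = GeneModel(
        gene_id="geneC", transcript_id="geneC.t1", chrom=chrom, strand="+",
        exons=[(110_000, 110_199), (110_500, 110_699)],
        biotype="ncRNA",
    )
    planted = [
        {"class": "exonic", "chrom": chrom, "pos": 100_150, "end": 100_160},
        {"class": "splicing", "chrom": chrom, "pos": 100_200, "end": 100_201},
        {"class": "ncRNA", "chrom": chrom, "pos": 110_050, "end": 110_060},
        {"class": "UTR5", "chrom": chrom, "pos": 100_020, "end": 100_030},
        {"class": "UTR3", "chrom": chrom, "pos": 101_320, "end": 101_330},
        {"class": "UTR3_UTR5", "chrom": chrom, "pos": 101_350, "end": 102_050},
        {"class": "intronic", "chrom": chrom, "pos": 100_500, "end": 100_510},
        {"class": "upstream", "chrom": chrom, "pos": 109_500, "end": 109_510},
        {"class": "downstream", "chrom": chrom, "pos": 103_500, "end": 103_510},
        {"class": "upstream_downstream", "chrom": chrom, "pos": 101_700, "end": 101_710},
        {"class": "intergenic", "chrom": chrom, "pos": 500_000, "end": 500_010},
    ]
    return [gene_a, gene_b, gene_c], planted


def simulate_gene_models(
    cfg: SimulationConfig, n_genes: int
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Non-overlapping random gene models plus a planted-region table.

    The first chromosome carries three hand-placed genes that guarantee
    one test coordinate per annotation class (returned in the planted
    table); ``n_genes`` further random genes (2-8 exons, 20% ncRNA,
    random strand) are scattered outside a reserved margin.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chrom_names = [c for c, _ in cfg.genome]
    chrom_lengths = dict(cfg.genome)
    models, planted = _planted_gene_models(chrom_names[0])
    reserved = {chrom_names[0]: [(1, 600_000)]}  # planted layout + margin
    occupied: dict[str, list[tuple[int, int]]] = {c: list(reserved.get(c, [])) for c in chrom_names}

    placed = 0
    attempts = 0
    max_attempts = 200 * n_genes + 200
    while placed < n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(f"genome too small to place {n_genes} non-overlapping genes")
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        n_ex = int(rng.integers(2, 9))
        exon_lens = rng.integers(80, 301, n_ex)
        intron_lens = rng.integers(200, 2001, n_ex - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        clen = chrom_lengths[chrom]
        if span + 2000 >= clen:
            continue
        start = int(rng.integers(1000, clen - span - 1000))
        end = start + span - 1
        if any(s <= end + 2000 and start - 2000 <= e for s, e in occupied[chrom]):
            continue
        exons = []
        cur = start
        for x, ex_len in enumerate(exon_lens):
            exons.append((cur, cur + int(ex_len) - 1))
            if x < n_ex - 1:
                cur += int(ex_len) + int(intron_lens[x])
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{placed + 1:04d}"
        if rng.random() < 0.2:
            model = GeneModel(
                gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom, strand=strand,
                exons=exons, biotype="ncRNA",
            )
        else:
            first, last = exons[0], exons[-1]
            u5_iv = (first[0], first[0] + 49)
            u3_iv = (last[1] - 49, last[1])
            if strand == "-":
                u5_iv, u3_iv = (last[1] - 49, last[1]), (first[0], first[0] + 49)
            cds = []
            for s, e in exons:
                cs, ce = s, e
                if s <= u5_iv[1] and u5_iv[0] <= e:
                    cs = max(cs, u5_iv[1] + 1) if u5_iv[0] <= s else cs
                    ce = min(ce, u5_iv[0] - 1) if u5_iv[1] >= e else ce
                if s <= u3_iv[1] and u3_iv[0] <= e:
                    cs = max(cs, u3_iv[1] + 1) if u3_iv[0] <= s else cs
                    ce = min(ce, u3_iv[0] - 1) if u3_iv[1] >= e else ce
                if cs <= ce:
                    cds.append((cs, ce))
            model = GeneModel(
                gene_id=gid, transcript_id=f"{gid}.t1", chrom=chrom, strand=strand,
                exons=exons, cds=cds, utr5=[u5_iv], utr3=[u3_iv],
            )
        models.append(model)
        occupied[chrom].append((start, end))
        placed += 1

    models.sort(key=lambda m: (m.chrom, m.start, m.end, m.transcript_id))
    return models, pd.DataFrame(planted)
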