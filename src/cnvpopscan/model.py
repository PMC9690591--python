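"""Core domain types for the CNV population-genomics pipeline.

Coordinates are VCF-native: 1-based, inclusive ``[pos, end]``. For an
insertion the interval degenerates to the single anchor base (``end ==
pos``). Any overlap arithmetic converts to 0-based half-open intervals at
the call site; the stored record round-trips bit-exactly through VCF.

Genotypes are diploid, biallelic, and reduced to four states; phased and
unphased calls are deliberately not distinguished because every downstream
statistic consumes alt-allele dosage only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Genotype",
    "SVType",
    "SVRecord",
    "CohortCallset",
    "GeneModel",
    "MergeConfig",
    "QCConfig",
    "SpectrumConfig",
    "DEFAULT_SEX_CHROMOSOMES",
]

DEFAULT_SEX_CHROMOSOMES = frozenset({"X", "Y"})


class Genotype(enum.IntEnum):
    """Diploid genotype state; the integer value is the alt-allele dosage."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class SVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"


@dataclass
class SVRecord:
    """One biallelic structural variant with per-sample genotype states.

    ``svlen`` keeps the VCF sign convention: negative for deletions,
    positive for duplications and insertions. For DEL/DUP the interval and
    the length are coupled, ``end - pos + 1 == |svlen|``; readers derive
    ``end`` from SVLEN so that records stay coherent regardless of whether
    the source file's END used the padding-base convention.
    """

    record_id: str
    chrom: str
    pos: int
    end: int
    svtype: SVType
    svlen: int
    genotypes: np.ndarray  # int8 vector of Genotype values, cohort order

    def __post_init__(self) -> None:
        self.svtype = SVType(self.svtype)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if abs(self.svlen) < 1:
            raise ValueError(f"{self.record_id}: |svlen| must be >= 1")
        if self.svtype is SVType.DEL and self.svlen >= 0:
            raise ValueError(f"{self.record_id}: DEL requires negative svlen")
        if self.svtype in (SVType.DUP, SVType.INS) and self.svlen <= 0:
            raise ValueError(f"{self.record_id}: {self.svtype.value} requires positive svlen")
        if self.svtype is SVType.INS:
            if self.end != self.pos:
                raise ValueError(f"{self.record_id}: INS requires end == pos")
        else:
            if self.end < self.pos:
                raise ValueError(f"{self.record_id}: end < pos")
            if self.end - self.pos + 1 != abs(self.svlen):
                raise ValueError(
                    f"{self.record_id}: interval [{self.pos},{self.end}] inconsistent "
                    f"with svlen {self.svlen} (require end - pos + 1 == |svlen|)"
                )
        bad = ~np.isin(self.genotypes, [g.value for g in Genotype])
        if bad.any():
            raise ValueError(f"{self.record_id}: invalid genotype codes {self.genotypes[bad]}")

    @property
    def length(self) -> int:
        """Event size in bp, |svlen|."""
        return abs(self.svlen)

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval for overlap arithmetic."""
        return self.pos - 1, self.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.end, self.svtype.value, self.record_id)

    def n_missing(self) -> int:
        return int((self.genotypes == Genotype.MISSING).sum())

    def copy(self, **changes) -> "SVRecord":
        if "genotypes" not in changes:
            changes["genotypes"] = self.genotypes.copy()
        return replace(self, **changes)


@dataclass
class CohortCallset:
    """An ordered SV callset over a fixed sample list, with optional
    population labels (attached by :func:`cnvpopscan.io.read_popmap`)."""

    samples: list[str]
    records: list[SVRecord] = field(default_factory=list)
    pop_of: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        n = len(self.samples)
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        for rec in self.records:
            if rec.genotypes.shape != (n,):
                raise ValueError(
                    f"{rec.record_id}: genotype vector length {rec.genotypes.shape[0]} != cohort size {n}"
                )
        if self.pop_of:
            missing = [s for s in self.samples if s not in self.pop_of]
            if missing:
                raise ValueError(f"samples without population label: {missing}")

    def sort_records(self) -> None:
        """Total, stable order: (chrom, pos, end, svtype, record_id)."""
        self.records.sort(key=SVRecord.sort_key)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s in self.pop_of:
                seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.pop_of.get(s) == pop]
        if not idx:
            raise KeyError(f"unknown or empty population label: {pop!r}")
        return np.asarray(idx, dtype=int)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneModel:
    """Transcript structure for annotation.

    Intervals are 1-based inclusive ``(start, end)`` tuples. For coding
    transcripts the CDS and UTR intervals partition the exons; ncRNA
    transcripts carry exons only.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "coding"  # "coding" | "ncRNA"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        if self.biotype not in ("coding", "ncRNA"):
            raise ValueError(f"{self.transcript_id}: bad biotype {self.biotype!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


def _check_fraction(name: str, value: float, low_open: bool = True) -> None:
    ok = (0 < value <= 1) if low_open else (0 <= value <= 1)
    if not ok:
        raise ValueError(f"{name} must be in {'(0,1]' if low_open else '[0,1]'}: {value}")


@dataclass(frozen=True)
class MergeConfig:
    """Group-level de-redundancy thresholds.

    Deletions merge at 50% reciprocal overlap, duplications at 90%;
    insertions use a breakpoint window plus a length-ratio gate because
    point events have no interval overlap. All gates also require
    genotype concordance >= ``concordance_min``; all inequalities are
    inclusive.
    """

    del_overlap: float = 0.50
    dupins_overlap: float = 0.90
    concordance_min: float = 0.95
    ins_breakpoint_window: int = 100

    def __post_init__(self) -> None:
        _check_fraction("del_overlap", self.del_overlap)
        _check_fraction("dupins_overlap", self.dupins_overlap)
        _check_fraction("concordance_min", self.concordance_min)
        if self.ins_breakpoint_window < 0:
            raise ValueError("ins_breakpoint_window must be >= 0")


@dataclass(frozen=True)
class QCConfig:
    """Site-level quality-control thresholds.

    Retained records satisfy |svlen| <= max_abs_svlen, excess-het exact
    p >= min_exchet_p, missing fraction <= max_f_missing and MAF strictly
    greater than min_maf.
    """

    max_abs_svlen: int = 10_000_000
    min_exchet_p: float = 0.05
    max_f_missing: float = 0.2
    min_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.max_abs_svlen < 1:
            raise ValueError("max_abs_svlen must be >= 1")
        _check_fraction("min_exchet_p", self.min_exchet_p)
        _check_fraction("max_f_missing", self.max_f_missing, low_open=False)
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")


@dataclass(frozen=True)
class SpectrumConfig:
    """Allele-frequency spectrum binning: ``n_bins`` right-closed bins
    ((k-1)/n, k/n]; sites at frequency 0 in the population are excluded."""

    n_bins: int = 10
    by_type: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
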