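# Methods

Statistical and algorithmic details of `cnvpopscan`. Notation: a cohort has
two diploid populations A and B; per variant, alt-allele frequencies are
written p_a and p_b; dosages are 0/1/2 copies of the alt allele.

## Data model

An `SVRecord` holds one cohort-level variant: chromosome, 1-based inclusive
interval `[pos, end]`, type (DEL/DUP/INS), signed `svlen` and one genotype
per sample (`HOM_REF=0, HET=1, HOM_ALT=2, MISSING=-1`). Invariants enforced
at construction:

* DEL has `svlen < 0`; DUP and INS have `svlen > 0`.
* For DEL/DUP, `end − pos + 1 == |svlen|`. VCF `END` is *derived from*
  `SVLEN` at parse time and never trusted independently, because htslib
  rewrites `INFO/END` for symbolic alleles from `SVLEN` on write — keeping
  the interval and `svlen` coupled makes round trips byte-stable.
* INS is a point event: `end == pos`, `svlen` is the inserted length.

VCF I/O uses pysam (symbolic ALTs `<DEL>`, `<DUP>`, `<INS>`; FORMAT `GT`).
GFF3 gene models are loaded through an in-memory gffutils database;
transcripts without CDS features become ncRNA models.

## Merging (group-level de-redundancy)

Two calls of the same type on the same chromosome are *linked* when both
gates pass:

* DEL/DUP: reciprocal overlap `min(|A∩B|/|A|, |A∩B|/|B|)` ≥ 0.50 (DEL) or
  0.90 (DUP), intervals 1-based inclusive.
* INS: breakpoint distance `|pos_A − pos_B|` ≤ 100 bp and length ratio
  `min(L_A,L_B)/max(L_A,L_B)` ≥ 0.9.
* Both: genotype concordance ≥ 0.95, computed over samples called in
  *both* records; a pair with no jointly called sample has concordance 0
  and is not linked.

Clusters are connected components under this relation (single linkage),
found by a sorted sweep with union–find: within each `(chrom, svtype)`
group records are sorted by position and each record is compared only
against neighbours that can still satisfy the positional gate, so the
sweep is near-linear in practice while provably equal to the brute-force
O(n²) partition (checked against that oracle in the tests). Each cluster
is represented by the member with the fewest missing genotypes, ties
broken by `(pos, end, record_id)`. Merging is idempotent and independent
of input order.

## Site QC

Four gates, applied independently (order-free; the tests verify all 4!
orders commute):

| gate | rule | default |
|---|---|---|
| length | `abs(svlen)` ≤ cap | 10 Mb |
| excess het | one-sided exact P(het ≥ observed) ≥ α | α = 0.05 |
| call rate | `F_MISSING` = missing/total ≤ cap | 0.2 |
| polymorphism | MAF > floor | 0 |

The excess-heterozygosity test uses the Levene–Haldane conditional
distribution of heterozygote count h given allele counts (n_A, n_B) in a
sample of n diploids; the upper tail P(h ≥ h_obs) is accumulated with the
numerically stable ratio recurrence
`P(h−2)/P(h) = h(h−1) / (4 (n_homA+1)(n_homB+1))`, starting from the
maximal heterozygote count. The implementation matches an independent
log-gamma closed-form oracle to < 1e−12 across every table with n ≤ 50.
Monomorphic sites get p = 1. Records with zero called genotypes fail the
call-rate gate (and the undefined MAF/ExcHet gates are reported as
failed).

## Differentiation scan

Per variant, Wright's fixation index in heterozygosity form:

```
p̄  = (p_a + p_b) / 2
Ht = 2 p̄ (1 − p̄)
Hs = [2 p_a (1 − p_a) + 2 p_b (1 − p_b)] / 2
Fst = (Ht − Hs) / Ht        (0 when Ht = 0)
```

Note `Ht − Hs = (p_a − p_b)² / 2`, so per-variant Fst is 1 exactly at a
fixed difference and 0 at equal frequencies. No sample-size (Weir–
Cockerham) correction is applied; small-n per-variant values are upward
biased, which leaves a rank-based top-percentile scan unaffected.
Frequencies use only called genotypes; records where either population is
entirely missing, and records on configured sex chromosomes (default
{X, Y}), are omitted from the scan.

**Selection rule.** With N scanned variants, the top `k = ⌈f·N⌉` by
`(Fst descending, record_id ascending)` are flagged, default f = 0.01; the
threshold reported is the k-th ranked Fst.

**Spectra and comparisons.** Frequency spectra use right-closed bins
`((k−1)/10, k/10]`; variants at frequency 0 in the population are
excluded. A variant is *present* in a population iff its frequency there
is > 0; shared/unique counts follow from presence in both/one population.

## Annotation

Each variant interval is classified against all transcripts within reach,
with hits resolved by precedence:

```
exonic > splicing > ncRNA > UTR3_UTR5 > UTR5 > UTR3 > intronic
       > upstream_downstream > upstream > downstream > intergenic
```

`exonic` means CDS overlap; `splicing` means overlap with the first/last
2 bp of an intron; `UTR3_UTR5` is a variant touching both UTR kinds.
Upstream/downstream are strand-aware 1000 bp windows beyond the
transcription start/end. Window sizes (`upstream_bp`, `splice_bp`) are
parameters.

## Structure

**Dosage matrix.** samples × variants, entries 0/1/2, missing entries
masked (never imputed as 0 in the matrix itself).

**PCA.** Missing dosages are imputed with the per-variant mean of called
samples; columns are centered and scaled by `sqrt(p(1−p))` with
`p = column mean / 2` (the normalization of EIGENSOFT/smartpca);
monomorphic and zero-variance columns are dropped. The sample covariance
`XXᵀ/m` is decomposed with a dense symmetric eigensolver; eigenvalues
below `max·1e−12` are treated as exact zeros, and eigenvector signs are
fixed deterministically (largest-magnitude loading positive), so results
are bit-for-bit reproducible.

**Distances and NJ.** Allele-sharing distance
`d(i,j) = mean(|dosage_i − dosage_j|)/2` over jointly called variants
(error if a pair shares none). The Saitou–Nei neighbor-joining algorithm
with the standard Q-criterion builds an unrooted tree; ties are broken by
the smallest index pair (deterministic output), negative branch lengths
are clamped to zero with the deficit moved to the sister branch, and the
tree is emitted as Newick. On additive (tree-metric) inputs NJ recovers
the generating tree exactly; the tests verify patristic distances match
random additive matrices at n = 4..8.

## Synthetic cohort generator

Defaults emulate a two-population resequencing design: 45 + 19 samples
("WBP"/"AWB"), 2000 variants on an 18-autosome genome of 20 Mb
chromosomes.

* Ancestral frequency `p ~ Uniform(0.05, 0.95)` per variant; population
  frequencies drawn independently from the Balding–Nichols distribution
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` with differentiation parameter F
  (default 0.2); F = 0 collapses to `p` exactly.
* Genotypes `Binomial(2, p_pop)` per sample: Hardy–Weinberg within
  populations, variants independent (no linkage).
* Types DEL/DUP/INS with mix (0.70, 0.03, 0.27); log-uniform lengths
  (50 bp–100 kb for DEL/DUP, 50 bp–1 kb for INS), uniform placement.
* A `dup_rate` fraction (default 0.10) of variants re-emitted as jittered
  near-duplicates. The jitter is clamped so the pair stays above the merge
  gates *by construction*: reciprocal overlap ≥ t tolerates at most
  `L(1−t)/(2(1+t))` per endpoint, giving bounds L/6 (DEL), L/38 (DUP) and
  the 100 bp window (INS). Genotypes are copied before missingness, so
  concordance stays near 1.
* Per-genotype missingness at rate 0.02.

A truth table records drawn frequencies and duplicate-of links. The
generator does **not** model linkage disequilibrium, mutation/genealogy,
variant-calling error profiles, overlapping variants of different types at
one locus, or sex chromosomes.

**Estimator expectation.** For frequencies drawn from Balding–Nichols,
`Var(p_pop) = F·p(1−p)`, hence `E[Ht − Hs] = F·p(1−p)` and
`E[Ht] = (2−F)·p(1−p)`; the ratio-of-averages estimate
`Σ(Ht−Hs)/ΣHt` therefore converges to `F/(2−F)` (0.111 at F = 0.2), not
to F. The test suite checks recovery against 99% Monte-Carlo intervals
around this expectation that were computed by an independent brute-force
simulation *before* the implementation existed.

Gene-model simulation places non-overlapping random genes (2–8 exons,
20% ncRNA, random strand) plus three hand-placed genes on the first
chromosome whose layout guarantees at least one test coordinate for every
one of the eleven annotation classes.

## Pipeline

`run_pipeline` executes simulate/load → merge → QC → popgen → annotate →
structure, writing every intermediate as a text artifact (VCF/TSV/Newick)
plus `manifest.json` listing per-stage outputs with sha256 digests and
wall times. All randomness flows from the single config seed, so reruns
are byte-identical (verified in the tests). Failures are wrapped with the
stage name.

## Limitations

* Per-variant Fst has no small-sample correction; use ranks, not absolute
  values.
* Mean imputation before PCA shrinks samples with much missingness toward
  the origin; acceptable at the default 2% missing rate.
* The exact-test recurrence is validated to n ≤ 50 diploids against the
  closed form; both routes are stable well beyond that, but very large
  cohorts were not a design target.
* The merge is single-linkage: long chains of borderline-overlapping
  calls can collapse into one cluster even when the extreme members do
  not overlap each other.
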