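# Methods

## Problem and model

`kindredx` enriches candidate disease-causing variants in X-chromosome exome
data from cohorts of affected males with X-linked recessive disorders of
high locus heterogeneity (the motivating case is X-linked intellectual
disability). Two facts drive the design. First, the male X outside the
pseudoautosomal regions (PARs) is hemizygous, so valid genotypes are 0 or 1
alternate copies, and unaffected males in reference populations cannot carry
a fully penetrant recessive disease allele — while unaffected heterozygous
females can. Second, causal mutations for such disorders are expected to be
rare and essentially private to families, so a variant key observed in two
or more *unrelated* affected samples is very unlikely to be causal, while a
causal variant in an affected relative pair must sit on the chromosome
segment the pair inherited identical by descent (IBD).

The pipeline composes, in order:

1. **Prefilters** (universal). A call is kept only if it has at least one
   alternate read on each sequencing strand, and if no other call in the
   same sample lies within 10 bp (inclusive; both members of a close pair
   are removed, distances evaluated once on the original call set, so the
   operation is idempotent and order-independent). Single-strand support and
   tight clustering are classic false-positive signatures.
2. **Affected-kindred / cross-cohort filter.** (i) Any key carried by two
   samples that are not declared kin is removed from *every* carrier —
   including a kindred pair that shares it with an unrelated sample. This
   also self-neutralizes batch-systematic artifacts, which recur across
   samples prepared in the same library. (ii) For each declared pair,
   pairwise IBD segments are detected (below) and a paired sample's variant
   absent in its kin is removed, unless the kin's depth at the site is
   below `min_depth` (default 4x), in which case absence is attributed to
   coverage and the call is kept. (iii) Survivors in paired samples are
   restricted to detected segment interiors. Sporadic samples skip (ii) and
   (iii).
3. **Clinical rescue.** Keys lost to the cross-cohort rule that carry a
   pathogenic or probable-pathogenic clinical annotation with population
   MAF < 1% are re-introduced in every original carrier and are immune to
   the database filters. This protects recurrent known mutations that arise
   independently in unrelated families.
4. **Database subtraction.** Sequentially: a "non-clinical" dbSNP-style
   panel (pathogenic records removed, then records below the allele-count
   cutoff removed — see below), a male-only population panel (records with
   at least one male carrier), and an EVS-style male panel (records
   annotated hemizygous, PARs masked).
5. **Gene scoring and enrichment.** Genes are ranked by weighted burden of
   qualifying variants and the prioritized list is tested for
   over-representation of known disease genes with the hypergeometric upper
   tail.

## IBD segment detection

For each pair, every (chrom, pos, ref, alt) key present in either sample
becomes a track point: concordant-alternate (A|A) if present in both,
discordant (A|R) otherwise. Inside a true IBD segment there should be no
A|R points apart from errors and rare de novo events. A candidate region is
any stretch that can host a window of `window_bp` (default 5 Mb) containing
at most `max_discordant_per_window` (default 0) A|R points. The sliding
window is evaluated exactly by an event-driven sweep over A|R-point gaps —
the dense limit of a stepped window, chosen so that with zero tolerance the
flagged stretches are *exactly* the maximal A|R-free intervals of at least
one window length (a `step_bp` argument provides the literal grid
evaluation). Overlapping flagged stretches merge; each merged boundary is
then refined to the midpoint between the outermost interior track point and
the nearest exterior A|R point (chromosome ends clamp). The refinement is a
deterministic, reproducible stand-in for the manual curation such analyses
traditionally applied. Segments are reported as 0-based half-open
intervals.

In the combined pipeline, cross-cohort-shared keys are removed *before*
tracks are built. Batch-systematic artifacts survive the prefilters by
construction (good strand balance, isolated positions) and would otherwise
scatter spurious A|R points through true segments; removing what the
cross-cohort rule already rejects makes detection robust without any manual
step.

## The female-carrier MAF cutoff

Database subtraction must not remove unannotated pathological variants. A
recessive X-linked disease allele can persist in a reference population
only in heterozygous female carriers, never in unaffected males. For a
variant observed `n` times among `M` male and `2F` female X chromosomes
(the reference population has M = 525 and F = 567, 1,659 chromosomes
total), the probability that all `n` copies sit in distinct heterozygous
females under random placement without replacement is

    P(n) = C(F, n) · 2^n / C(M + 2F, n),   P(n) = 0 for n > F.

`min_count_for_cutoff` returns the smallest `n` with P(n) ≤ p_max; at
p_max = 1% this gives n = 12 (P = 0.0096), i.e. MAF ≈ 0.72% of 1,659.
Records at or above 12 copies are safe to subtract. The cutoff is
parameterized as a copy *count* rather than a rounded frequency because the
count form is exact. A plain all-copies-on-female-chromosomes model
(`model="chromosome"`, C(2F, n)/C(M+2F, n), homozygotes allowed) is also
implemented; it yields 1.02% at n = 12 and would push the cutoff to 13.
The carrier model is the default because carrier females are the
biologically relevant reservoir.

## Relatedness and stratification

Pairwise identity is `2·|A ∩ B| / (|A| + |B|)` on full variant keys. A
declared pair should be each other's best match, standing out as a Tukey
box-whisker outlier (best match > Q3 + 1.5·IQR of the sample's identity
distribution); the 1.5 multiplier is configurable since the convention is a
formalization of a visual check. Stratification compares each sample's
carrier profile to the cohort mean (residual sum of squares in cohort
standard-deviation units) and reports the mean reference-population allele
frequency (two populations, A and B) over the sample's panel-matched
variants.

## Gene scoring

Only splicing or non-synonymous coding changes qualify. Default weights:
missense 1; splicing, nonsense, frameshift 2; synonymous, intronic and
other 0. A variant retained in both members of a pair multiplies its weight
by `pair_bonus` (default 2). Each distinct variant key contributes once.
The numeric values formalize ordinal statements (truncating > missense >
silent; pair-shared counts extra) and are fully configurable; ties break
deterministically by (LoF presence, qualifying-variant count, gene id).
Enrichment of `k` known genes among `n` listed, from `K` known in the
`N`-gene target set, is the hypergeometric upper tail
`P(X ≥ k)`; the fold is `(k/n)/(K/N)`. A mutation-rate-weighted baseline
(`Σ counts over known / Σ counts over all` from a control cohort) is
reported alongside, not substituted into, the unweighted test.

## Synthetic cohorts

The generator emulates the study design end to end: 30 sporadic males plus
26 affected pairs (22 brother, 2 maternal half-brother, 1 maternal
first-cousin, 1 uncle–nephew) on a 155 Mb chromosome with PARs masked.
Each pair descends from founder haplotypes; a Poisson number of
recombination breakpoints per meiosis (rate 1.8/meiosis, snapped to 2 Mb
linkage-block boundaries) partitions the chromosome, and each interval is
IBD with probability 2^-(meioses-1) (brothers and maternal half-brothers 2
meioses, uncle–nephew 3, cousins 4 — brothers share about half the
chromosome in expectation). Haplotypes draw alternate alleles from a
10,000-site panel with Beta(0.2, 2) frequencies plus ~30 private rare
variants per founder haplotype; private variants travel with their
haplotype, so pairs are discordant only outside shared intervals. One
causal variant per family (absent from every panel) is planted inside a
shared interval of at least 10 Mb for pairs, anywhere for sporadic samples.
Depth is Poisson(49); alternate reads split binomially between strands
(causal sites are guaranteed ≥ 12x with ≥ 2 reads per strand — a callable
mutation, not a marginal one). Variant density (~1,000/sample) is scaled
below the real ~1,800/sample for speed; all counts are configurable.

Injected error classes, each disjoint from causal keys and spaced ≥ 25 bp
from true calls so classes do not interact: strand-biased false positives
(all reads one strand), clustered runs of 2–3 calls within 10 bp,
batch-systematic keys planted in ≥ 2 unrelated samples of one library
batch with realistic read support, and residual pair-discordance noise
inside shared intervals (strand-biased, so the prefilters remove it — the
erroneous in-segment A|R points seen in raw data).

Reference panels are finite binomial samples of the site table: carrier
counts over 525 male and 1,134 female chromosomes (dbSNP-like), an
EVS-like male/female draw with hemizygous annotation, and
clinical-significance flags on a configurable fraction of low-MAF records.
Each panel additionally ascertains only a fraction of segregating sites
(dbSNP 0.97, population-male 0.30, EVS-male 0.45), reflecting how much of a
real cohort's calls those databases actually match — without this, a
simulated panel is an implausibly complete census and every database filter
removes nearly everything. With these defaults the standalone filter
efficiencies on synthetic cohorts fall in the ranges reported for real
X-exome data (database filters from ~25% to ~94%; the kindred/cross-cohort
filter the strongest single reducer).

What the generator does **not** emulate: capture design and coverage
heterogeneity, alignment and calling artifacts beyond the four error
classes, linkage disequilibrium within blocks, indels' representation
ambiguities, and population admixture beyond a two-population frequency
split. Passing tests therefore demonstrate the pipeline's logic and its
constructed guarantees, not performance on real patient data.

## Numerical and degenerate-input choices

- "Within 10 nucleotides" is inclusive (distance ≤ 10 rejects).
- Variant matching everywhere is exact on (chrom, pos, ref, alt);
  multi-allelic VCF records are split on read.
- VCF positions are 1-based; segments, BED and PAR masks are 0-based
  half-open.
- Strand counts come from FORMAT fields `ADF`/`ADR` (alt-only, Number=1) or
  a sidecar TSV; which fields carried strand counts is a dialect choice and
  both names are configurable.
- Absent a per-sample low-coverage track, a missing call in the kin is
  treated as a confident reference call (depth queries need pileups, which
  are out of scope).
- An all-zero genotype collection, an empty overlap in concordance, and an
  identity of two empty call sets raise explicit undefined-statistic
  errors rather than returning a value.
- With zero cohort variance the stratification deviation is reported as 0
  for every sample.
- `carrier_probability` uses exact integer binomials; no floating-point
  cancellation is possible.

## Known limitations

- The cross-cohort rule's power grows with cohort size; on very small
  cohorts a database filter can legitimately remove more than it.
- Segment detection with a nonzero discordance tolerance merges overlapping
  tolerant windows, so a merged segment can locally exceed the tolerance;
  with the default zero tolerance segments are exactly A|R-free.
- The enrichment test treats genes exchangeably; the weighted baseline
  quantifies, but does not correct, unequal genic mutation rates.
- Rescue depends entirely on the completeness of the clinical annotation
  panel supplied.
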