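# Methods

## The estimand

A tandem repeat locus is an annotated reference interval `[start, end)`
(0-based half-open everywhere in this package) with a repeat unit of
`unit_len` bp. The annotated span need not be a whole number of units —
published annotations are frequently inexact about boundaries — so all
arithmetic treats the span and the unit length as independent quantities.

For one read aligned across the locus, the quantity of interest is the
signed copy-number change relative to the reference,

    delta_bases = I − D
    delta_units = round(delta_bases / unit_len)   (ties away from zero)

where `I` is the total number of inserted read bases whose attachment
coordinate lies in `[start − n, end + n)` and `D` is the total number of
reference bases of `[start, end)` deleted in the read. The margin `n`
(default 10 bp) exists because repeat boundaries are fuzzy: a small margin
makes it unlikely that an unrelated nearby insertion is attributed to the
repeat, at the cost of missing expansions of repeats whose true extent
exceeds the annotation. The asymmetric definition — insertions counted in
the margin-extended window, deletions only inside the annotated repeat —
reflects that the margin's purpose is insertion attribution; a deletion
entirely outside the annotated repeat removes flanking sequence, not
repeat copies. This definition, and nearest-integer rounding with ties
away from zero, are the two places where an independent implementation of
this estimator has latitude; both are validated against the simulator's
ground truth rather than against any external tool.

Only *spanning* reads are genotyped: the alignment must have aligned
(non-gap) columns strictly before `start − n` and at or beyond `end + n`,
anchoring both repeat boundaries in unique flank. Reads split into
multiple alignment blocks are treated block-by-block; an observation
requires a single block to span the locus, which avoids chimeric-join
artifacts at the price of discarding split coverage.

## Canonical unit classes

Reading a repeat from a different phase or the opposite strand rotates or
reverse-complements its unit, so units are classified up to cyclic
rotation and reverse complement. A unit is first reduced to its minimal
period (homopolymers of any length collapse to the single-base class),
then the class representative is the lexicographic minimum over the ≤ 2k
equivalent strings. Because the field's display names are not the
lexicographic minima (the literature writes "CAG" and "GGC", not "AGC"
and "CCG"), a small alias table maps representatives to conventional
names for the ten triplet classes and the quintuplet disease class.
Enumeration over all 4^k k-mers of minimal period exactly k yields the
classes; for k = 3 there are 10, matching the conventional count.

## Per-locus cohort statistics

Deltas from all spanning reads of all samples are pooled per locus; the
summary is mean, median, Q1, Q3 and IQR = Q3 − Q1 of the pool, where
quantiles use linear interpolation between order statistics
(h = (n − 1)q). This convention is forced by the published tables, which
contain fractional quartiles (e.g. Q3 = −1.25 at a 3-bp-unit locus) that
nearest-rank rules cannot produce. Absolute lengths convert a delta
quantile to base pairs, `floor(ref_span + unit_len × q)`; flooring reproduces
every published quartile-length cell of the packaged disease catalog.
Published mean-length cells are printed from higher-precision means than
the one-decimal means shown, so the catalog's mean-length column is
carried as data but not asserted row-by-row.

Per-read pooling (rather than per-individual genotypes) is the survey's
polymorphism measure; per-sample delta lists are retained in the joined
table for detection-rate reporting. Loci with fewer than 3 pooled reads
are flagged low-coverage but never dropped. Background comparison sets
are uniform draws without replacement from non-disease loci of the same
canonical class and genic region, 10 sets by default, reproducible by
seed. The GWAS proximity filter keeps loci with IQR ≥ 5 whose distance to
a catalog SNP is < 100 bp (distance 0 inside the locus, otherwise the
minimum distance to either boundary base); a 10 kb threshold serves the
broader near-by search used for phasing candidates.

## Genic regions

refFlat gene models assign each locus a region by overlap priority
coding > 5′UTR > 3′UTR > noncoding exon > intron > intergenic across all
overlapping transcripts, with UTR sides resolved by transcript strand.
The gene symbol is taken from the transcript that supplies the winning
region.

## Allele splitting and phasing

A diploid individual's per-read deltas are sorted and every split point
is scored by total within-group sum of squares; the minimum is the exact
1-D two-means solution (n ≤ a few hundred reads, so exhaustive scanning
is cheap and deterministic). Each allele is represented by the median of
its member reads. If the two representatives differ by less than 2 units,
or either group holds fewer than half the minimum read count (default
minimum 3 reads), the call is homozygous and both alleles share the
pooled median. The 2-unit homozygosity gap and the vote threshold below
are conservative defaults exposed in the API; no published value exists
for either.

Each allele's SNP base is the majority base its member reads carry over
the SNP position, requiring at least 2 voting reads and a 0.6 majority;
otherwise the base is missing but the length genotype is still reported.
This per-read extraction plus vote replaces the original workflow's
consensus-assembly-and-realignment step; at per-locus scale the two carry
the same information, but the vote does not benefit from consensus error
correction, which is a documented fidelity gap of this implementation.
Reverse-strand alignments are stored in reference orientation (MAF shows
the reverse-complemented read), so no further complementing is applied at
extraction.

Association across individuals uses allele-level absolute lengths
(ref_span + unit_len × allele delta) grouped by SNP base and an unpaired
two-sided t-test, equal-variance by default with Welch as an option. With
more than two observed bases the two largest groups are compared. Groups
with zero variance and equal means return t = 0, p = 1; perfectly
separated groups are clamped to the smallest positive float so p stays in
(0, 1].

## The simulator

The generator emulates the study conditions the analysis targets: a
cohort of 21 diploid individuals (the surveyed cohort size) at 27×
default coverage (the cohort's average), on a small reference with
embedded repeats. Defaults chosen where no study value exists: a 12 kb
genome with 3 kb ± 300 bp reads, so that a mid-genome locus is spanned by
most reads at realistic per-locus depth; one (CAG)×10 locus with allele
spectrum {0: 0.5, +10: 0.5}, a clean two-allele problem ten units apart;
error rates default to zero so that the noise-free contract (exact truth
recovery) is the baseline, with 2%/2%/2% substitution/insertion/deletion
used as the noisy condition in tests.

Haplotypes are drawn independently (Hardy–Weinberg); under complete LD
the alternate SNP base rides exactly on haplotypes whose delta exceeds
the allele-distribution median; under an r² setting the haplotype's
long-allele indicator is copied with probability √r² and otherwise drawn
from its marginal, giving correlation √r² in expectation; "independent"
ignores the repeat. Each haplotype's repeat-length change is placed as a
single contiguous insertion or deletion run at a unit boundary near the
locus midpoint — how aligners typically represent repeat-length variants —
which keeps the read-level delta oracle exact. Reads are sampled
uniformly per haplotype with normal lengths, emitted fully aligned (no
soft-clipped tails) on a random strand, as MAF blocks that are valid
alignments of the emitted read sequences; noise is injected per base in
the order substitutions, insertions, deletions, with an optional indel
rate boost inside repeat spans modelling the elevated indel error of
nanopore reads in low-complexity sequence. Unique flanks are scrubbed of
exact tandem structure (period up to the longest embedded unit, 3+
copies) and locus-adjacent bases are forced not to extend the repeat run,
so the embedded annotation is exactly the maximal run.

What the simulator does **not** model: basecalling signal artifacts,
context-dependent or strand-biased error profiles, chimeric reads,
mapping ambiguity (alignments are emitted as ground truth, not produced
by an aligner), somatic mosaicism, and structural variation other than
repeat-length change. Passing tests therefore demonstrate correctness of
the estimator and statistics pipeline given approximately correct
alignments; they do not certify performance on real nanopore data, where
alignment quality around long expansions is the dominant error source.

## Numerical and degenerate-input choices

* Rounding of delta units: nearest integer, ties away from zero
  (`floor(|x| + 0.5)` with the sign restored).
* Quantiles: numpy's "linear" method, equivalent to h = (n − 1)q
  interpolation; a single read makes Q1 = median = Q3.
* Allele split ties: the first split point achieving the minimal cost
  (scanning left to right over the sorted list) wins; read identity
  breaks delta ties in the sort, making member sets deterministic.
* Majority-vote ties at exactly the threshold pass; a 50/50 vote fails
  the 0.6 threshold and yields a missing base.
* Empty delta pools yield "undetected" rows with no numeric fields
  rather than NaNs; empty inputs to quantile or to the IQR fraction
  raise.
* The tandem-repeat detector resolves overlapping candidate runs
  longest-first (ties: leftmost, then smallest period), reports each run
  under the minimal period of its unit, and in mismatch-tolerant mode
  trims runs so they never end in tolerated mismatches. It is an exact
  periodicity scanner for test-scale sequences, not a probabilistic
  masker; genome-scale annotations are expected to be read from BED or
  simpleRepeat tables.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run cohorts of 21 diploids on
8–24 kb genomes at 10–27× coverage (roughly 600–2 300 reads per cohort),
200 power and 500 type-I replicates at the population level, and 10 kb
sequences for the detector oracle. These sizes give stable pass/fail
behavior for the stochastic properties (the binomial slack at n = 21×2
alleles and 500 replicates is accounted for in the asserted bands) while
keeping a full run in the tens of seconds.

## Known limitations

* The delta definition is a reconstruction validated against the built-in
  simulator, not a byte-for-byte reimplementation of any external
  genotyper; margin semantics at the window boundaries may differ from
  other tools in single-base ways.
* Homozygous-by-length individuals whose two haplotypes carry different
  SNP bases are reported homozygous with whatever base the pooled vote
  produces (or missing on a split vote); read-backed resolution of such
  cases would require haplotype-aware alignment, which is out of scope.
* The equal-variance t-test is the default on the grounds of convention;
  allele-level length distributions at strongly bimodal loci violate
  normality, and the type-I property is only verified at the shipped
  cohort size.
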