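# Methods

This note records the models, parameter choices and numerical decisions
behind the package, in the order the pipeline runs.

## Barcode extraction

A barcode is accepted at read offset *o* when the 9-nt upstream anchor
matches exactly at *o*−9, the 9-nt downstream anchor matches exactly at
*o*+20, every barcode base is A/C/G/T and has Phred quality ≥ 20 (≈ 1%
error).  The offset may deviate from its expected position by at most ±2 nt;
when several offsets qualify, the one closest to the expected position wins
and equidistant ties go to the smaller offset.  Anchors are configuration,
not constants — they are vector-specific, so `FlankSpec` is user-supplied
and the simulator ships its own.  Reads with a barcode containing N are
rejected outright even though the quality gate would usually catch them.

Single-substitution sequencing errors create spurious barcodes at Hamming
distance 1 from a real one.  The one-off filter keeps a barcode iff it has
no distance-1 neighbour in the table or its count is at least **twice** the
count of its most abundant neighbour; "at least two times" is implemented
inclusively (≥ 2×), the comparison is against the single most abundant
neighbour (not the sum), and every barcode is judged against the original
unfiltered table so the result is order-independent.  Neighbour lookup
enumerates the 60 distance-1 sequences against a hash of observed barcodes
(O(n·60)); no approximate index is needed at any realistic scale.

## Library characterization

*Pairs.* Barcode-pair reads carry both barcodes in one read (two
`FlankSpec`s at different offsets).  Reads where only one barcode extracts
are unusable, not errors.  After per-tag one-off filtering, chimeric-PCR
pairs — artifacts that join the UP barcode of one plasmid to the DOWN
barcode of another — are removed by the same 2× logic applied to *related*
pairs (pairs sharing an UP or a DOWN barcode).

*Junction mapping.* The genomic tail downstream of the barcode (minimum
15 nt) is aligned by exact 15-mer seeding against a genome k-mer index,
ungapped extension, and a single-indel rescue that re-anchors the suffix at
±1 nt.  A candidate qualifies when its longest exact block is ≥ 15 nt, it
has ≤ 1 indel and ≥ 90% identity; the identity floor is this package's
choice (the block/indel rules alone admit arbitrarily poor flanks).  Tails
with zero or multiple qualifying locations (repeats) are discarded; hits
within 10 nt on the same strand are clustered as one location, absorbing
indel off-by-ones.  Pre-computed PSL alignments can be imported and pass
through the same acceptance rules.  Each barcode then keeps its dominant
junction only if that junction has ≥ 2× the reads of every alternative.

*Join.* Coordinates are 0-based half-open in memory and 1-based inclusive
in exported TSVs (stated in their headers).  A junction is the first
genomic base of the insert adjacent to the barcode's anchor, with a
direction flag for which way the insert extends.  Joining requires the two
junctions on one contig, facing inward, spanning 100–6000 nt.  The
inward-facing check is an addition beyond the length rule: it rejects
joins of junctions that cannot come from one molecule.  Fragments are
stored strand-agnostically (start < end); insert orientation is retained by
the simulator as metadata but unused downstream because gene coverage is
interval containment.  Barcode uniqueness across fragments is enforced;
violators are dropped and counted.

## Counting

Counts are taken on UP barcodes by default (the two tags give nearly
identical fitness readouts, so sequencing one suffices); a `tag="down"`
mode exists for concordance checks.  No depth normalization occurs at the
count stage — the fitness log-ratio plus median centering is the only
normalization.  Per sample, column sums plus the unmapped tally equal the
usable reads; the pipeline logs these so every read is accounted for.

## Fitness scores

A barcode is *valid* for an experiment set when it has ≥ 10 reads in at
least one of the set's time-zero samples.  For a valid fragment,
f = log₂((s+1)/(t+1)) with t the **sum** over the set's time-zero samples
(not the mean), then f is centered by the experiment's median over valid
fragments.  The +1 pseudocounts are applied exactly as written.

Gene scores solve min‖Ag − f‖² subject to g ≥ 0 (scipy's active-set NNLS),
with A the binary fragments × genes complete-coverage matrix (inclusive
interval containment, strand-agnostic).  Ordinary least squares badly
overfits this design; non-negativity suppresses the spurious negative
compensation that inflates neighbours of causative genes.  Detrimental
effects come from a second pass against −f.  The two passes are merged as
`score = score_pos − score_neg`: for genes with coherent fragment evidence
at most one side is active, so the subtraction reduces to whichever pass
found the effect.  Each condition sample is solved independently;
replicates are never pooled before regression.  Genes covered by no valid
fragment are reported as missing, never as zero.  Intergenic-only effects
are not modeled in the single-gene pass; adjacent-gene pair columns (set
for fragments covering both genes and hence the intergenic region between
them) absorb them in the epistasis model.  A pair passes when its score
exceeds both single-gene scores, it is supported by ≥ 2 fragments, and
this holds in every replicate.

The clone-count helper implements N = ln(1−P)/ln(1−insert/genome), rounded
up.  For 3-kb inserts in a 4.7-Mb genome at P = 0.99 the formula gives
≈ 7213; a commonly quoted figure of ~4600 for these inputs corresponds to
roughly P = 0.95 and does not follow from the formula as printed — the
formula is implemented as written and the discrepancy left alone.

## Effect calling

Three per-experiment filters define a *reliable* effect:

1. **Magnitude** — |score| ≥ 2, using the regression score (it is "the"
   gene score; the fragment mean is biased for bystander genes).
2. **Consistency** — one-sample two-tailed t-test (n−1 df) of the covering
   fragments' f against a reference r: r is the mean of all fragment scores
   in the experiment when that mean shares the gene score's sign (absorbing
   centering uncertainty, and slightly more stringent), else 0; pass iff
   p < 0.05.  Zero-variance degenerate input passes with p = 0 when the
   mean differs from r, else fails.  Single-fragment genes cannot be
   t-tested; they pass iff |f| is in the top 1% of the experiment's valid
   fragment scores (valid-only: scores exist only for valid fragments).
3. **Noise** — |z| ≥ 4 with z = mean(f)/noise, noise propagated per
   fragment as √(1/(1+s) + 1/(1+t))/ln 2 (Poisson best case, with
   count_start = the summed time-zero count, consistent with f's
   denominator) and per gene as √Σν²/n.  At |z| ≥ 4 with ~4300 genes the
   standard-normal null predicts ≈ 0.27 false calls per experiment.

Reliable effects are *high confidence* with ≥ 2 supporting fragments, or —
because a single plasmid can carry a secondary mutation — with a ≥ 2
|score| in another experiment of the same compound.  Replicate consistency
is |score| ≥ 1.5 with matching sign in the partner replicate.

The FDR estimate permutes the barcode → fragment assignment uniformly at
random (the coverage structure of fragments is untouched; only which
barcode's counts sit on which fragment changes), recomputes **mean** gene
scores, re-applies the full calling, and repeats 10 times (default);
FDR = mean(shuffled count)/actual count, not-applicable when nothing
genuine was called.  Mean scores (not regression) are used in the shuffled
data, which if anything overestimates the FDR.  All randomness is
explicitly seeded.

The operon comparison takes a user-supplied table of first-in-transcript
vs later genes (rows with weak evidence and genes appearing in both
categories are excluded by the loader) and tests the 2×2 association with
a two-sided Fisher exact test, summing hypergeometric probabilities ≤ the
observed table's.

## The simulator

The simulator emulates the study conditions the analysis is tested under:
a 50 kb single-contig random genome with 40 non-overlapping gap-separated
genes (400–1200 nt); 500 fragments with Normal(2600, 800) nt lengths
clamped to the 100–6000 nt cloning window at uniform positions (matching
the ~2.6 kb mean insert of real libraries of this design), cloned in
random orientation with unique random barcode pairs; 2 time-zero samples
and 2 condition replicates at a mean depth of 100 reads per fragment.
Counts are Poisson around a log-normal (σ = 0.5) per-fragment baseline —
the simplest generative model consistent with the Poisson counting-noise
formula used by the filters.  A condition multiplies each fragment's
abundance by 2^Σβ over the genes it fully covers and rescales to constant
total depth (a pooled assay measures relative abundance); growth is thus
collapsed into the fold change and β is the recovery target, with no
explicit generations parameter.  Read-level defaults: 10 reads per
pair/junction, 60-nt genomic tails, flat Q30 qualities, configurable
per-base substitution rate and chimeric-read rate (chimeras pair barcodes
from different fragments and are truth-labelled in read names).

What the simulator does **not** emulate: instrument-specific error and
quality profiles, PCR duplicates and amplification bias beyond chimeras,
indel sequencing errors, multi-contig or repetitive genomes (beyond tests
that plant explicit repeats), operon structure, and expression-level
variation — a gene's effect is a fixed β whenever covered, whereas real
fragments express genes conditionally on captured promoters.  Passing
tests therefore demonstrate correctness of the computational method under
its own noise model, not robustness to every artifact of real libraries.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in seconds while every statistical property is still
sharply testable: 15–40 genes, 60–500 fragments, depth 100–500.  NNLS
solutions are checked against an exhaustive coarse-to-fine nonnegative
grid enumeration (final step 0.01) on instances up to 4 genes × 8
fragments; optima need not be unique (duplicated coverage columns), so the
oracle comparison uses fitted values and objective where degeneracy is
possible.  Median centering is exact to float rounding (< 1e−9 asserted).
The t-test uses n−1 degrees of freedom, two-tailed; Fisher's test is
two-sided by probability mass.  Degenerate inputs: empty fragment sets
yield empty results (not exceptions), zero-total samples yield
not-applicable percentages, and sets without time-zero samples are
configuration errors.

## Known limitations

* One known-red validation: ranking recovered scores against injected β
  with Spearman's correlation saturates near 0.6 on the standard study even
  when recovery is numerically excellent (Pearson ≈ 0.997, every injected
  effect within counting noise, neutral neighbours < 0.1).  With 35 of 40
  genes tied at β = 0, midrank Spearman exceeds 0.9 only if essentially all
  null genes score *exactly* zero, and the two-pass NNLS leaves small
  nonzero noise scores on about half of them.  The magnitude-based checks
  are the informative ones for recovery quality.
* The negative pass inherits a small systematic bias: when a noticeable
  fraction of fragments carries positive effects, the experiment median
  sits slightly above the null center, so null fragments center slightly
  negative (~0.2 standard errors of fragment noise).
* Junction mapping assumes a sequenced source genome; unsequenced sources
  and metagenomic multi-genome references are out of scope, as is
  demultiplexing (assumed done upstream).
* The single-gene model attributes fitness only to completely covered
  genes; effects requiring more genes than a fragment can carry, or
  partial-gene (truncation) effects, are invisible.
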