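# Methods

This note documents the models, parameter choices and numerical decisions
behind `retroinvade`, and what the synthetic benchmarks do and do not show
about real data.

## Copy-number model

The haploid copy number of a TE family is the ratio of its mean
per-position read coverage to the pooled mean coverage of a set of
single-copy genes. The estimator assumes (i) reads sample the genome
uniformly, (ii) the normalization genes are present exactly once per
haploid genome, and (iii) reads from any copy of the family map to the
family consensus. Violations show up as biases: diverged copies lose reads
at the identity threshold (the estimate then reflects *consensus-like*
copies, which is the quantity of interest for dating recent invasions), and
repetitive or low-complexity regions attract spurious coverage.

Two guards address the second failure mode:

* **Poly-A curbing.** Homopolymer runs of ≥8 bp in the consensus (the run
  length is configurable; 8 is long enough that random sequence almost
  never reaches it and short enough to catch real poly-A tracks) attract
  reads from every A-rich region of the genome. Coverage inside an
  annotated run is replaced by the median of the 50 bp flanks on each side
  before averaging.
* **Ambiguity tracking.** A read whose best alignment score ties across k
  references contributes coverage 1/k to each, kept in a separate
  "ambiguous" layer. Ambiguous coverage enters the copy-number numerator
  (those reads do come from somewhere in the family set) but never base
  counts or SNP calls, where the identity of an ambiguously placed read is
  unreliable.

## Internal aligner

The internal aligner exists so that the pipeline is testable end to end
without an external mapper; externally produced SAM is ingested on equal
terms (path equivalence is asserted in the tests). It is ungapped by
design: seed (exact 13-mers at ~13 bp stride, plus one terminal seed) and
score every candidate diagonal over all references and both strands with
match +1 / mismatch −1. Reads may overhang reference ends; the overhang is
soft-clipped and unscored, with a 30 bp minimum aligned span. Placements
below 75% identity over the aligned span are dropped. Indels in reads
surface as mismatch runs or fall below the identity floor — acceptable
because every downstream statistic consumes coverage and base counts, not
gap placements. Ties across references mark ambiguity (above); ties within
a reference resolve to the plus strand, then the smallest start, so results
are order- and permutation-invariant.

Consequences worth knowing: consensus ends carry a ~25 bp coverage ramp
(reads overlapping an end by less than the minimum span are lost), a <1%
effect at kb consensus lengths that cancels between TE and gene coverage;
and the two identical LTRs of a freshly modelled element are internally
ambiguous, so all pure-LTR reads stack on the 5′ copy — the mean coverage,
and hence the copy number, is unchanged.

## Invasion status and timeline

The three-way call is thresholded, not visual: `absent` below 0.2 copies;
`recent` requires breadth ≥0.8 **and** mean read divergence ≤5%;
everything else is `degraded_only`. The thresholds live in the run config.
They are deliberately coarse — recent invasions produce near-complete
breadth and ~1% divergence while ancient remnants produce patchy coverage
at ~20% divergence, so the decision boundaries sit in empty space. The
divergence condition makes the classification monotone: increasing read
divergence can only move a call away from `recent`.

The timeline of a family is the interval (t_low, t_high) where t_low is the
latest collection year up to which every sample is non-recent and t_high
the earliest year from which every sample on is recent. Mixed years (an
invasion in progress) fall inside the interval. A family recent everywhere
yields (−∞, earliest year); absent everywhere yields no interval. Samples
without a collection year are a hard error.

Year groups are compared per family with the two-sided Wilcoxon rank-sum
test: exact p-values for combined n ≤ 25 without ties, the tie-corrected
normal approximation otherwise, p = 1 when all values coincide. No
multiple-testing correction is applied by default across the family screen;
Benjamini–Hochberg adjustment is available via a flag.

## TE composition

SNP frequencies are fractions of a family's dispersed copies carrying an
allele, estimated from unambiguous base counts at sites with coverage ≥10
and minor frequency ≥0.1 (both configurable). The cross-sample matrix
keeps the union of SNP keys; a site covered in a sample but lacking the alt
scores 0, an uncovered site is missing. Filtering keeps biallelic SNPs
(one observed alt per site) present in more than 3 samples, and is
idempotent.

PCA runs on the column-centered matrix via SVD; missing entries are imputed
to the column mean first (variance-neutral — the imputed entries contribute
nothing to the centered column). Frequencies are used raw by default;
per-column standardization is a flag, since the relative weighting of
high- and low-frequency SNPs is a modelling choice, not a correctness
question. Component signs are fixed by making each component's
largest-magnitude loading positive, so runs are comparable. A degenerate
matrix with no columns is an error; a non-empty matrix with zero variance
(identical samples) returns all-zero coordinates, which is the honest
answer rather than a failure.

Diagnostic SNPs for a population are columns with mean frequency ≥0.3
inside and ≤0.1 in every other population (both configurable), ranked by
the inside–outside gap. The ablation experiment re-runs the PCA without
them; on panels with planted founder-effect lineages this collapses the
clustering while removing an equal-sized random set does not.

## Ping-pong signature

Overlap k counts the overlapping nucleotides between a sense and an
antisense read's 5′ ends, so the canonical ping-pong peak is k = 10 —
conventions in the literature differ by ±1 and this one is pinned in the
code. o(k) = Σ_p sense5′(p)·antisense5′(p+k−1) for k = 1..23 (bounded by
the minimum piRNA length), and z10 is the z-score of o(10) against the
other 22 values. z10 is reported as undefined when the background has
fewer than two nonzero entries or zero spread (e.g. a constructed
pure-signal set), and flagged when reads map to only one strand.
Adapter trimming cuts at the leftmost prefix match of the adapter with ≥3
nt overlap and ≤1 mismatch per 10 bases, then filters to 18–36 nt.
Multi-mapping small RNAs count 1/k per tied family, consistent with the
genomic ambiguity convention.

## Donor scoring

The internal repeat-hit finder is seed (12-mer) and gapless x-drop
extension (drop 20, match +1 / mismatch −1) of every family against both
strands of each contig; hits contained inside a higher-scoring hit of the
same family (the LTR-in-LTR self-repeat case) are suppressed.
Defragmentation merges same-contig/family/strand hits with genomic gap
≤100 bp whose consensus spans advance in hit order (50 bp overlap
tolerance); the colinearity requirement keeps tandem copies apart, and a
distance-only mode reproduces plain merge-by-distance behaviour. Merged
score is the fragment sum, merged divergence the length-weighted mean, and
the operation is idempotent.

Similarity s = max(score in assembly)/max(score over all assemblies) is
computed on defragmented hits (a pre-merge mode is available); it is
scale-invariant in the scores, 1 for the best assembly by construction, 0
for assemblies without hits, and reported missing — not 0/0 — for families
without hits anywhere. LTR dating uses age = d/(2·rate) with d the gapless
mismatch fraction between the terminal repeats; the substitution rate has
no default and must be supplied explicitly, because any built-in value
would silently parameterize a headline number.

## Synthetic data: what it shows and what it does not

The generator reproduces the statistical structure the analysis relies on:
copy numbers 0–40 per haploid genome, lineage SNPs drawn independently per
copy at population-specific frequencies, recent copies at ~0.5% divergence
beside degraded fragments at exactly their stated divergence, uniform
single-end reads of 50/100 bp with substitution errors, 23–29 nt small
RNAs with a planted 10 nt 5′-overlap pair fraction, and donor assemblies
along an exact divergence ladder. Truth tables are exact recounts of the
emitted sequence, and every output is byte-deterministic given a seed
(each generator derives its stream from (seed, role), so reusing one seed
across generators never replays the same randomness).

Not modelled, deliberately: ancient-DNA damage (C→T deamination) — the
robustness control for degraded historical material is read length (50 vs
100 bp), not a damage model; paired-end structure; indel sequencing
errors; realistic base-quality profiles (no stage uses qualities); genomic
repeat landscape beyond the planted TEs (the backbone is i.i.d. uniform
ACGT, so cross-mapping in tests isolates aligner behaviour rather than
genome complexity). Passing benchmarks therefore demonstrate correctness
of the estimators under their stated assumptions, not robustness to
library-preparation artifacts of real historical specimens.

## Benchmark problem sizes

The synthetic study scenarios run at desk scale by choice: 5 kb consensus
elements with 400 bp LTRs and three 6 kb normalization genes for the
copy-number ladder {0, 2, 5, 10, 20, 40} at 20× coverage (kb-scale
sequences keep the read-sampling noise of the coverage ratio near 2–3%,
well inside the 10% recovery criterion); a 12-sample, 1-family panel at
15× for the timeline; 24 samples × 30 SNPs with 20 copies per sample for
the composition panel; 1,500 read pairs (signal) and 100×200 pairs (null)
for ping-pong; a 4-step divergence ladder with 2 copies per family for
donor ranking; 1,000 replicates of the 9-vs-16 design for test
calibration. The full acceptance run completes in well under a minute on
one CPU.

## Known limitations

* The aligner's ungapped model undercounts coverage for indel-rich copies;
  ingest external SAM for those.
* Gene-coverage normalization inherits any copy-number variation of the
  chosen genes in real strains.
* `build_timeline` assumes classification errors are rare; a single
  misclassified sample widens (never flips) the interval only if it sits
  at the interval edge.
* Similarity ranking identifies the most consensus-like donor *candidate*;
  it cannot, by itself, establish the direction of a horizontal transfer.
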