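# Methods

## Coordinate conventions and interval algebra

All internal coordinates are 0-based half-open (BED convention); GTF input
(1-based closed) is converted on read. Overlap means ≥ 1 shared base and is
strand-blind throughout, for peaks and loci alike. Outputs are sorted by
(chromosome lexicographic, start, end) so repeated runs diff cleanly.
Chromosome-name mismatches between inputs (`chr1` vs `1`) are *not*
auto-harmonised: an intersection over disjoint namespaces logs a diagnostic
and returns empty, because silent renaming hides data errors. `intersect`
merges each input per chromosome and sweeps both lists jointly, emitting
maximal half-open runs covered by both sets; `slop` extends by a symmetric
flank clamped to `[0, chromosome length]`.

## Peak classification and enhancer-to-gene assignment

Peaks are classified into a single category with the fixed priority
**promoter > exon > intron > intergenic**, where the promoter region of a
gene is `[TSS − w, TSS + w)` with w = 1000 bp by default. The priority
order and window mirror the defaults of the standard peak-annotation
tooling; candidate enhancers are the intron and intergenic peaks.

Assignment is *soft*: a candidate enhancer is linked to **all** genes whose
TSS lies within the assignment window (default 35 000 bp, inclusive at the
boundary), not only the nearest, so CRE–gene links are many-to-many.
Distance is measured from the CRE midpoint to the TSS — symmetric and
robust to peak width — and is signed positive when the TSS lies at a
greater genome coordinate than the midpoint, independent of gene strand.
Midpoint-based, all-in-window assignment is a recorded design choice;
edge-based or nearest-only variants would be straightforward alternatives
but are not what this pipeline implements.

## Motif model and exact p-values

A PWM stores per-position base probabilities (A,C,G,T). Scores are
log-odds in bits against an order-0 background (uniform by default,
overridable per matrix); a pseudocount c = 0.001 regularises probabilities
as (p + c)/(1 + 4c) before the logarithm so no score is −∞.

The null distribution of the score of a random background word is computed
exactly by dynamic programming: each per-position score is rounded to an
integer lattice of step g = 1/1000 bit, and the distribution of the sum is
built by convolving one position at a time (cost O(width × support)). The
survival function of that lattice gives p-value(s) = P(S ≥ s). Windows are
scored *on the same lattice*, so for any width ≤ 8 the DP survival
function agrees with exhaustive enumeration of all 4^w background-weighted
words exactly (this is asserted in the test-suite). A configured support
cap (2×10⁷ lattice points) guards against granularities too fine for wide
matrices; the error message advises coarsening. Discretisation error is
bounded by the mass of words within `width` lattice steps of the
threshold; halving g moves any p-value by less than that bound.

Scanning covers both strands by default: the minus strand is handled by
scanning the reverse-complemented matrix (with its own null distribution,
exact under any background) over the forward sequence, so minus-strand
hits carry plus-strand coordinates. Windows containing N are skipped; all
windows with p ≤ 0.001 are reported without overlap masking (downstream
logic needs only "≥ 1 hit", and masking would add unstated behaviour). No
multiple-testing correction is applied across windows: the threshold is a
plain per-match p-value. Several matrices are combined with OR semantics
(`scan_multi`); a region "harbours a motif" iff the union of hits is
non-empty. For reporter deletion-construct design, `delete_motif` excises
the hit with the lowest p-value (ties to the leftmost start).

## Target calling

Active enhancers = intersect(ATAC, H3K27Ac) with promoter/exon fragments
removed; intersection precedes classification, so a fragment inside an
exon is dropped even when its parent peaks extend beyond it. Fragments are
the countable CRE unit and inherit a stable `chrom:start-end` id.
Expression-enriched genes satisfy fold change > 2 **and** FPKM > 10, both
strict. A gene is called iff it is enriched and receives ≥ 1 motif-bearing
CRE within the window; a CRE assigned to several enriched genes supports
all of them and is counted once in `n_cres`. The gene universe for
counting is the expression table. Called genes are therefore monotone in
both the p-value threshold and the window size.

## Disease loci

Loci arrive as coordinate spans (cytogenetic bands must be pre-resolved to
coordinates) with an optional causative gene; loci are split on that
field. Unresolved loci are extended by 100 bp on both sides and a gene is
"in a locus" when its gene span (not its TSS alone) overlaps an extended
locus by ≥ 1 bp — spans are the recorded choice because locus boundaries
come from coarse mapping. The cross-reference reports k targets in loci
out of n, with the percentage rounded half-up to the nearest integer
(36/156 → 23). Enrichment is P(X ≥ k) with X ~ Hypergeom(N, K, n), where
the universe N is the provided gene table and K its members inside
extended unresolved loci; both are echoed in the result because the
appropriate universe is an analysis decision, not a constant. Significance
is declared at α = 0.1, one-tailed.

## Assay statistics

Percent input corrects the input-chromatin Ct for the fraction of
chromatin assayed: adjusted input Ct = Ct_input − log₂(1/fraction), then
percent input = 100·2^(adjusted − Ct_IP). One qPCR cycle is exactly a
factor of two; the dilution adjustment is standard qPCR arithmetic and the
fraction is a required input. The *ratio paired t-test* is the classic
paired t-test applied to log₂(xᵢ/yᵢ) (base 2 to match cycle arithmetic):
t = mean(d)/(sd(d)/√n), df = n − 1, one-tailed upper p for "treatment
greater". Zero-variance differences are flagged indeterminate rather than
mapped to a degenerate p-value. The DE threshold filter keeps genes with
log₂FC > 1.5 and adjusted p < 0.1 (strict); a direction-blind |log₂FC|
variant is available by flag, and genes passing at *either* of two
developmental stages are combined by union (`de_filter_union`).

## Synthetic-study design

The generator writes a complete study — FASTA genome, chromosome sizes,
gene-model TSV, ATAC and H3K27Ac BED, MEME-minimal matrices, expression
TSV, ortholog TSV, locus TSV and a truth JSON — and is byte-deterministic
given its config (all randomness flows from one seed).

Defaults: 3 chromosomes × 100 kb of i.i.d. uniform background sequence,
30 genes (three exons each, span 2.7 kb), 12 expression-enriched genes of
which 5 are planted targets, three width-6 consensus matrices at consensus
probability 0.97, CREs of 400 bp realised as ATAC/H3K27Ac peak pairs whose
intersection is exactly the intended fragment, and six decoy classes
(ATAC-only, H3K27Ac-only, promoter pairs, exon pairs, motif-free
enhancers near enriched genes, motif-bearing enhancers near non-enriched
genes), three of each. Uniform order-0 background matches the scanner's
default so planted-site p-values are exactly controlled: at width 6 and
consensus probability 0.97 the exact consensus word is the *only* window
passing p ≤ 0.001 (consensus p = 4⁻⁶ ≈ 2.4×10⁻⁴; the best mismatch scores
p = 19/4096 ≈ 4.6×10⁻³).

Placement is anchored rather than free: each chromosome has two isolated
target slots (at 8 % and 52 % of its length), a cluster of enriched
non-target genes near the right end, and dedicated decoy zones, each
jittered per seed. The slot geometry guarantees every planted enhancer
lies within 35 kb of exactly one enriched gene and > 35 kb from every
other enriched gene, which is asserted at generation time. Planted sites
are verified by scanning; decoy enhancers are verified motif-free, with
the local background resampled under a retry cap when a chance hit
appears. End-to-end precision = recall = 1 on the called gene set is
therefore a constructed property of the study, verified across seeds —
the tests demonstrate correct composition of the pipeline's set logic,
scoring and thresholds, not statistical robustness to violated
assumptions. Features of real data the generator deliberately omits:
non-uniform (GC-biased, repeat-rich) background, peak-shape and
replicate-level noise, motif variants diverging from the consensus,
chromatin-contact-informed assignment, and genome-scale gene density.
Problem sizes throughout (toy genome, 20-seed recovery runs, widths ≤ 8
for enumeration cross-checks) are chosen so the whole suite runs in
seconds while every oracle remains exhaustive.

## Numerical and degenerate-input choices

- p-values are clamped into (0, 1]; a survival function at or below the
  minimum lattice score is exactly 1.
- Empty peak/gene inputs produce empty outputs with logged warnings, not
  errors; an empty motif-hit list for deletion, an empty target set for
  cross-referencing, and inconsistent contingency counts are errors.
- BED/MEME/locus parsers report the offending line, motif or row;
  MEME probabilities round-trip to 10⁻⁶ (written at 8 decimals).
- Ties: nearest-TSS reporting breaks distance ties by gene id; motif
  deletion breaks p-value ties by leftmost start; all tables are written
  in a fixed sort order.

## Known limitations

- The enrichment universe and the locus tables are inputs; the package
  makes no claim about externally published counts that depend on
  database versions.
- Only order-0 backgrounds are supported for motif scanning (no
  dinucleotide model, no q-values).
- GTF reading expects explicit `gene`/`exon` features with `gene_id`
  attributes; transcript inference is out of scope, as are BigWig/BAM
  inputs and liftOver.
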