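# cretarget

Identification of putative transcription-factor target genes from
epigenomic peak data, built for regulatory-genomics analyses of the kind
used to nominate candidate disease genes from developmental enhancer maps
(e.g. SIX1 targets in inner-ear progenitors as candidate deafness genes).

The pipeline composes four ideas:

1. **Active enhancers** are regions supported by both open chromatin and
   the H3K27Ac mark: the per-base intersection of ATAC and H3K27Ac peak
   sets, with fragments overlapping promoters (±1 kb of a TSS) or exons
   removed. Surviving fragments are the countable cis-regulatory-element
   (CRE) unit.
2. **Soft annotation** links each CRE to *every* gene whose TSS lies
   within a 35 kb window of the CRE midpoint, allowing many-to-many
   CRE–gene relationships.
3. **Motif scanning with exact p-values.** A motif is a position weight
   matrix (PWM); a window w of motif length is scored by the log-odds
   S(w) = Σᵢ log₂(pᵢ(wᵢ)/b(wᵢ)) against an order-0 background b. The
   p-value of a score s is P(S ≥ s) under the null that the window is
   drawn from b, computed *exactly* by dynamic-programming convolution of
   the per-position score distributions on a discretised lattice
   (granularity 1/1000 bit). Hits are windows with p ≤ 0.001, both
   strands. A gene is called a putative target iff it is
   expression-enriched (fold change > 2 and FPKM > 10) and receives at
   least one motif-bearing CRE.
4. **Disease-locus enrichment.** Candidate targets are cross-referenced
   against disease loci whose causative gene is unknown (loci extended by
   100 bp; genes overlapping by ≥ 1 bp counted), and enrichment is tested
   with the one-tailed hypergeometric (Fisher) test
   P(X ≥ k), X ~ Hypergeom(N, K, n), at α = 0.1.

Supporting statistics for the accompanying bench assays are included:
ChIP-qPCR percent-input normalisation (100·2^(adjusted input Ct − IP Ct)),
the ratio paired t-test (paired t on log₂ within-pair ratios), the classic
paired t-test, and the differential-expression threshold filter
(log₂FC > 1.5, adjusted p < 0.1).

A seeded synthetic-study generator emits a complete toy study — genome,
gene models, peaks with planted consensus motif sites, expression table,
ortholog map, disease loci — with full ground truth recorded, so every
stage is testable offline.

## Worked example

```sh
cretarget simulate --out study --seed 4
cretarget call-targets --out run \
    --atac study/atac.bed --h3k27ac study/h3k27ac.bed \
    --genes study/genes.tsv --expression study/expression.tsv \
    --motifs study/motifs.meme --fasta study/genome.fa
head -6 run/targets.tsv
```

prints

```
gene_id	n_cres	n_hits	cres
g001	1	1	chr1:3806-4206
g002	1	1	chr2:3534-3934
g003	1	1	chr3:3591-3991
g004	1	1	chr1:47840-48240
g005	1	1	chr2:47837-48237
```

The five called genes are exactly the five planted targets recorded in
`study/truth.json`: each is expression-enriched and supported by one
active enhancer (`chrom:start-end`) that carries one motif hit at
p ≤ 0.001. Decoy constructions — ATAC-only and H3K27Ac-only peaks,
promoter- and exon-overlapping peak pairs, motif-free enhancers near
enriched genes, and motif-bearing enhancers near non-enriched genes — are
all correctly rejected. `run/manifest.json` records the thresholds and
input digests needed to reproduce the run; the same library calls are
available in Python via `cretarget.run_target_pipeline`.

The same study feeds the locus stage:

```sh
cretarget loci-enrich --out enr --loci study/loci.tsv \
    --genes study/genes.tsv --targets targets.txt \
    --sizes study/genome.chrom.sizes
```

which writes `enr/enrichment.json` with the cross-reference count, the
rounded percentage of targets in unresolved loci, and the one-tailed
hypergeometric p-value with its (k, n, K, N) contingency.

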