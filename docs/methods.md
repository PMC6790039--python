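# Methods

## Scope and model

`saltlnc` implements the post-assembly analysis used to catalogue
salt-stress-responsive long non-coding RNAs in a plant genome and to relate
them to single-base DNA methylation. It takes assembled transcript models
(GTF), a reference gene annotation, a genome sequence, repeat/TE tracks,
per-transcript attributes (coding-potential score, protein-database hit,
FPKM per condition), and per-cytosine methylation reports, and produces:

1. a **filtration cascade** that classifies transcripts as lincRNAs or
   lncNATs with complete per-stage accounting,
2. **characterization statistics** of the classified sets, and
3. **methylation-ratio (RMC) aggregations** over genes, promoters, fixed
   chromosome windows, and metagene coordinates.

Because the full study requires deep sequencing data, the package ships a
synthetic-study generator with planted ground truth; every analysis is
validated end-to-end against what was planted.

## Coordinates and interval algebra

All internal coordinates are 0-based, half-open, forward-strand; GTF/GFF
(1-based inclusive) is converted at the I/O boundary only, which keeps
off-by-one reasoning out of the analysis code. Two conventions matter
downstream:

- *Adjacency*: half-open intervals that touch (`a.end == b.start`) overlap
  by 0 bases and have gap distance 0. "Within X nt" tests therefore use
  `gap_distance < X`, with overlapping features counted as distance 0.
- *Gap across chromosomes* is undefined and raises an error rather than
  returning 0, so a missing-chromosome bug cannot masquerade as proximity.

Ambiguity codes (N) pass through sequence extraction unchanged; AU content
counts A+T over unambiguous A/C/G/T positions only, so undetermined bases
do not bias composition either way.

## The filtration cascade

Stages run in a fixed order, and each transcript is removed at the first
stage it fails, giving the accounting identity
`input = Σ removals + lincRNAs + lncNATs` that the audit object enforces:

1. **Sense overlap** — ≥1 bp span overlap with an annotated gene on the
   same strand; removed transcripts are the mRNA set kept for
   characterization.
2. **Housekeeping RNAs**, then **miRNA precursors** — overlap with
   blacklist loci on either strand or listed ids; a transcript matching
   both lists counts as a housekeeping removal (first stage wins).
3. **Coding potential** — score strictly greater than 0.5 removed
   (0.5 itself kept).
4. **Homology** — any protein-database hit at e-value ≤ 1e-5 removed.
5. **Length** — spliced length < 200 nt removed (200 kept).
6. **Expression** — FPKM < 2 under *both* conditions removed; 2.0 in
   either condition keeps the transcript, and a transcript silent in
   control but expressed under salt is retained (those become the
   "activated" expression class).
7. **Adjacency** — intergenic transcripts with a same-strand
   protein-coding gene closer than 200 nt removed (exactly 200 kept);
   transcripts that overlap a gene antisense bypass this stage because
   they are on the lncNAT path. A both-strand proximity mode exists
   behind a flag.
8. **Final classification** — antisense span overlap with any annotated
   gene ⇒ lncNAT, else lincRNA.

Overlap granularity is genomic span for both the sense exclusion and the
antisense test; exon-level intersection is available behind a flag but is
not the default, since span overlap is what "transcribed from the opposite
strand of a gene" means at locus resolution and the coverage statistic
(below) measures span containment. Gene-level tallies count distinct
`gene_id`s among the final transcripts.

## Characterization

- **Repeat/TE overlap**: "by number" is the fraction of transcripts with
  ≥1 bp exonic overlap; "by length" is pooled — total exonic bases covered
  by the *merged* feature set divided by total exonic bases, so stacked
  repeat annotations are never double-counted. Exonic (not genomic-span)
  denominators are used because transcripts are the measured objects.
- **TE composition**: per-superfamily shares of TE-covered exonic bases
  within TE-overlapping lincRNAs (codes RLG, RLC, DTM, DTH, DTC, DHH);
  the companion number is the mean per-transcript TE-covered fraction
  among those lincRNAs. A per-transcript-majority mode exists for
  comparison.
- **AU content**: (A+T)/(A+C+G+T) per spliced sequence; coding transcripts
  contribute separate 5'UTR/CDS/3'UTR partitions (only where annotated).
  ECDFs are nondecreasing step functions ending at 1.
- **lncNAT coverage**: overlap(NAT span, gene span)/NAT span length,
  maximized over antisense genes; "entirely covered" means coverage = 1.
- **Expression classes**: activated (control 0, salt > 0), silenced (the
  reverse), up-/down-regulated (both positive, ratio beyond 2-fold,
  strict), else unchanged. Fold change uses the raw FPKM ratio with no
  pseudocount — the zero-denominator cases are precisely the activated/
  silenced classes, so a pseudocount would blur the distinction the
  classes exist to make. Induced = activated + up-regulated; class
  differences are tested with a Pearson 2×2 chi-square without continuity
  correction (configurable), appropriate at the scale of thousands of
  transcripts.
- **Windows**: transcripts are assigned to the fixed window containing
  their span start (deterministic and order-free); the last partial
  window is kept; counts conserve class totals by construction.
- **Nearest genes**: gap distance over both strands; ties break to the
  smaller distance, then sense orientation, then lexicographic gene id.
- **Conservation**: presence = ≥1 hit at e-value ≤ 1e-5 per target
  genome, from externally produced tabular hit files; the package never
  runs the aligner.

## Methylation ratios (RMC)

A cytosine site is *called* when its coverage reaches `min_cov` and
*methylated* when it has ≥1 methylated read. The published analysis does
not state its site-call rule; this binary ≥1-read rule is the natural
reading of a ratio-of-methylated-cytosines statistic, with `min_cov`
(default 1 for simulated data, where reads are exact; 4 recommended for
real data) guarding against single-read noise. The RMC of a region and
context is methylated/called sites, both strands pooled; no-call sites
enter neither numerator nor denominator, and empty regions are undefined
(NaN), never 0.

- **Context calling** enumerates every C on the forward strand and every
  G (a reverse-strand C) with its strand-local trinucleotide: CG ⇒ CpG,
  CHG, CHH with H ∈ {A,T,C}. A cytosine at a chromosome end is kept when
  its context is already determined (a terminal CG) and skipped when the
  truncated trinucleotide leaves CHG/CHH ambiguous; Ns likewise skip only
  when they leave the context undetermined.
- **Promoters** are the fixed 1 kb immediately upstream of the
  strand-aware start, clipped at chromosome boundaries.
- **Window RMCs** are pooled site ratios per fixed window (1 Mb on a real
  genome; the analysis drivers use 10 kb on the toy genome), matching the
  region-ratio definition rather than a mean of per-gene ratios.
- **Metagene profiles** use 20 upstream bins of 50 bp plus 60
  length-scaled body bins by default (bin counts unstated in the original
  analysis; these resolve the along-gene shape at both real and toy gene
  lengths and are configurable). Bins run 5'→3', so minus-strand genes
  reverse both the upstream direction and the body order. Per gene and
  bin an RMC is computed, then averaged over genes with ≥1 called site in
  that bin. Sites are points, so a gene shorter than the bin count still
  contributes every called site to exactly one bin — short genes are
  never skipped, they simply leave some bins empty.
- **Condition ratios** are per gene/region/context `rmc_sa / rmc_wt`,
  undefined and flagged when the control RMC is 0 or either side is
  undefined.
- **Never-methylated** genes have zero methylated CpG and CHG calls over
  the gene body (CHH is deliberately excluded, as in the original
  definition).

## The synthetic study

The generator is a pure function of its configuration (seed included;
reruns are byte-identical). Defaults are the study conditions: 2
chromosomes × 250 kb, 40 coding genes, 50 lincRNAs, 20 lncNATs, one decoy
per cascade stage.

- **Placement** is sequential with inter-feature gaps of at least twice
  the 200-nt adjacency threshold, which *guarantees* planted lincRNAs
  pass the adjacency stage and overlap nothing. lncNATs are planted
  antisense within gene spans (72 % fully inside, the remainder extending
  past the 3' boundary, mirroring the observed "entirely transcribed"
  share). Infeasible packing raises an error suggesting a larger
  chromosome.
- **Decoys** each fail exactly one stage by construction (a sense-overlap
  straddler, blacklist-locus overlappers, a coding-potential score > 0.5,
  a planted protein hit, a 120–199 nt transcript, FPKM < 2 in both
  conditions, and a transcript 40–180 nt from a same-strand gene), so the
  per-stage audit counts are predictable from the configuration.
- **Expression**: lncRNA classes are drawn as 55 % activated + 20 %
  up-regulated (≈75 % induced, with activated dominating because the
  observed salt/control median FPKM of lincRNAs was positive/zero);
  mRNAs get 5 % + 25 % (≈30 % induced). All planted true positives pass
  retention (score ≤ 0.5, no hit, FPKM ≥ 2 in at least one condition).
- **Methylome**: every cytosine's binary state is Bernoulli with the
  observed per-context rates (0.637 CpG / 0.436 CHG / 0.04 CHH under
  control, shifted by −0.02 under salt — the observed alterations were
  slight and downward); coverage is Poisson(10) and all reads agree with
  the site state. Binary site truth matches the binary-site RMC
  statistic; a beta-binomial per-site-rate model would add a parameter
  the statistic cannot see.
- **TE track**: 87 % of the span of a quarter of lincRNAs is covered by a
  TE with superfamily drawn ≈ RLG 0.68 / RLC 0.21 / DNA families the
  rest, plus unconstrained background TEs and unlabeled simple repeats.

What the generator does **not** emulate: read-level noise (bisulfite
conversion errors, mapping bias), replicate structure, overlapping gene
models, centromeric repeat gradients, realistic base composition (the
genome is uniform random, so H-base composition is ≈ uniform over A/T/C
rather than A/T-biased), and intronic lncRNAs. Passing tests therefore
demonstrate the correctness of the algorithms and accounting under the
stated generative model, not the biological values a real dataset would
give; dataset-dependent percentages (42.9 % repeat overlap, 63.7 % CpG
methylation, …) are recovered only insofar as they are planted.

## Problem sizes

Tests and the analysis drivers run the default 2 × 250 kb study
(~120 planted transcripts, ~300 k cytosine sites); oracle-equivalence
checks use hundreds of randomized small instances; methylation-rate
recovery uses a 40–80 kb genome per seed, where 3 binomial SDs is a
sub-percentage-point tolerance. These sizes make every planted guarantee
exact while keeping a full run in seconds.

## Known limitations

- Span-level (not exon-level) overlap is the default for sense exclusion
  and antisense detection; exon-level mode exists but is untested against
  a published count, since no such count exists to disambiguate.
- The adjacency stage tests same-strand protein-coding neighbours only by
  default; whether the original exclusion also applied to antisense
  neighbours is unresolved, so the both-strand variant is a flag.
- The never-methylated statistic depends on the site-call rule; with
  deeper real data and `min_cov` 4 the fractions shift, which is why both
  knobs are exposed.
- GO enrichment, aligner execution (CPC, BLAST, bisulfite mapping), and
  DMR segmentation are out of scope.
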