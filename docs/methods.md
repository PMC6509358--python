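# Methods

This note documents the models, conventions and design choices behind
`jellyseq`, module by module, including what the synthetic-data generator
does and does not emulate.

## Coordinates, formats and stranded chemistry

All internal coordinates are 0-based half-open. GFF3 is 1-based closed at
the file boundary; BED and bedGraph are 0-based half-open; the conversion
happens once, in `formats`. The minimal SAM dialect supports `@SQ`
headers, the FLAG bits for strand/mate/pairing, `POS`, and CIGAR strings
consisting only of `M`: the screen and the counting operate on intervals,
not alignments, so spliced or clipped records are rejected rather than
approximated. BAM/CRAM are out of scope.

Libraries are stranded TruSeq-style, i.e. dUTP chemistry: the sense strand
of a sequenced fragment is the alignment strand of mate 2 (mate 1 aligns
antisense). `composition.fragment_sense_strand` encodes this;
an `fr` protocol (mate 1 = sense) is available behind the
`--stranded-protocol` flag.

## The putative-dsRNA screen (`duplex_screen`)

A duplex candidate is a pair of a forward- and a reverse-strand read on
the same reference, in the same sample, with

- overlap = min(ends) − max(starts) ≥ `min_overlap` (default 25 nt),
- |start difference| ≤ `max_overhang` and |end difference| ≤ `max_overhang`
  (default 100 nt),
- distinct molecules: `fragment_id` inequality when `exclude_mates` is on
  (default). The two mates of one fragment are one RNA molecule even
  though they align to opposite strands, so a mate pair can never be a
  duplex.

**Strand semantics.** Under dUTP chemistry every well-covered gene yields
reads on both alignment strands, so screening raw alignment strands calls
pairs of same-sense molecules throughout the transcriptome. The pipeline
therefore replaces each read's strand by its fragment's sense strand
before the screen (`composition.sense_corrected_reads`); after this
correction, "opposite strands" means opposite *molecules*. A
`--raw-strands` mode is kept for data where the correction is not wanted;
there, mate exclusion is the load-bearing guard.

**Algorithm.** Per (sample, reference), both strand lists are sorted by
start and joined with a sliding window: |start difference| ≤ max_overhang
is a necessary condition for a call, so only reverse reads whose start
lies within ±max_overhang of the forward read's start are examined. Worst
case degrades to all-pairs within the window. The implementation is
property-tested against a brute-force all-pairs oracle on random
instances, and every emitted candidate is re-validated against its own
invariants rather than trusted.

**Deduplication and classification.** Unique duplexes are keyed by
(reference, overlap_start, overlap_end) — the overlap is the duplexed
region, so it is the natural identity; union-interval keying is available
via `dedupe_key="union"`. The reported duplex length is the overlap
length. A unique duplex is assigned to every gene whose span intersects
the overlap interval, strand-agnostically (a duplex has both strands);
with no intersecting gene its class is "unannotated", otherwise the
highest-priority biotype among assigned genes (tRNA > pre-miRNA >
protein-coding > other), so a duplex touching a tRNA gene is reported as
duplexed tRNA. Per-gene counts increment every intersecting gene once per
sample in which the duplex has support.

**Normalization.** Median-of-ratios (DESeq-style): for genes whose counts
are positive in every sample, the per-sample factor is the median ratio of
the count to the gene's geometric mean across samples. Note the exact
equivariance: scaling one sample's counts by c moves its factor by
c^((m−1)/m) (the geometric-mean reference rescales too) and its factor
*relative to the others* by c; scaling all samples alike leaves factors
unchanged. When no gene is positive everywhere the operation fails with a
pointer to the mean-ratio alternative.

## Composition, Welch test, coverage (`composition`)

Fragments (mate-merged pairs) are assigned to a gene iff their interval
overlaps the gene span and their sense strand equals the gene strand.
Fragments eligible for two or more genes are ambiguous and dropped from
gene-level counts (the conventional default of gene-level counting);
fragments overlapping no gene are tallied as "Other" (unannotated
regions). Gene spans, not exon models, are used — the toy annotation has
no exon structure, which matches gene-level counting at this scale.

Species-level composition counts **every** mapped fragment of a reference
toward its species: viral fragments count regardless of strand (antisense
viral RNA is real library content), and ambiguous bee fragments appear as
an explicit "ambiguous" row so species totals are not biased by the
gene-level dropping rule. Within the bee, rows are biotypes. Groups below
`min_fraction` (default 1%) in every sample are collapsed out of the
report but retained in the full table.

Size factors are mean-ratio: sample total / mean of sample totals, so the
factors average to exactly 1. The Welch two-sample t statistic, its
Welch–Satterthwaite degrees of freedom and the two-sided Student-t p-value
are implemented from the textbook formulas (cross-checked against
`scipy.stats.ttest_ind(equal_var=False)` in the tests) and applied to
normalized species totals within each fraction group (per-sample fractions
are available behind a flag). Strand-specific coverage is per-base depth
per strand; `log10p1` applies log10(x+1) elementwise. Axis flipping for
antisense tracks is presentation only — tracks are emitted unflipped with
strand labels.

## GO overrepresentation (`go_enrich`)

The universe is every gene with a count ≥ 2 in at least one sample; terms
with fewer than 5 annotated genes in the universe are dropped. GO is taken
as a flat gene→term table; ontology-DAG ancestor propagation is out of
scope.

The length-bias correction estimates P(gene ∈ interest set | gene length)
by splitting the universe into ~10 equal-occupancy length bins, taking the
per-bin interest fraction, smoothing with isotonic regression against the
bin mean length, evaluating at each gene's length (mean of the gene's
transcript lengths) and clipping to (ε, 1−ε), ε = 10⁻³. This is a
deliberately simple, monotone stand-in for a spline probability-weighting
function. A term's Wallenius odds is the odds ratio of the mean weight
inside vs outside the term, and the p-value is the upper tail of the
Wallenius noncentral hypergeometric distribution
(`scipy.stats.nchypergeom_wallenius`), which at odds 1 reduces exactly to
the central hypergeometric (checked against combinatorial enumeration for
every configuration with a universe ≤ 20, and against a draw-by-draw
dynamic-programming oracle at odds ≠ 1). Terms are flagged at raw
p < 0.05 by default — no multiple-testing correction, matching the
protocol being re-implemented; Benjamini–Hochberg is available behind a
flag.

## Binding models and fitting (`binding_mst`)

The binding-event equation is the exact 1:1 ligand-depletion solution,
evaluated in the cancellation-free form θ = 2P / (S + √(S² − 4PL)) with
S = P + L + K_d. The hyperbolic approximation P/(P+K_d) is recovered as
L → 0 but is wrong when K_d is comparable to the labeled-RNA
concentration — which is the case for a ~4 nM phase with labeled RNA
defaulting to 5 nM — hence the quadratic form throughout. The labeled
concentration is configurable.

A multiphasic curve is baseline + Σ amplitude_j · θ(P; K_d,j, L): the
binding events are treated as independent and additive over a shared
labeled species. Mixing the 16-step dilution series 1:1 with the labeled
RNA is read as equal volumes, halving both concentrations; the simulator
applies the dilution and the curve carries in-capillary values.

Fitting is derivative-based least squares (`scipy.optimize.least_squares`,
TRF) over (baseline, log10 K_d of the tightest phase, nonnegative
log10-K_d gaps, nonnegative amplitudes); the gap parameterization enforces
K_d ordering. Eight starts are used: one with K_ds spread evenly across
the titration range in log space and seven drawn from a seeded uniform
log-K_d lattice. The phase count is selected by
BIC = n·ln(RSS/n) + k·ln(n) with k = 2·(phases) + 1 free parameters.
Self-association is S(C) = s0 + Δs·C^h/(K_d,app^h + C^h) with h fixed to 1
unless freed.

Recovery is judged at 2-fold in K_d: with MST-scale noise (1–2% of the
dynamic range) and 16-point designs, the tightest and loosest phases of a
nanomolar-to-tens-of-micromolar ladder are not constrained better than
that; the tolerance is configurable in the tests. Amplitudes and baseline
are recovered exactly at zero noise (the data lie in the model class).

Unit helpers parse nM/µM/mM strings, form fold-excess ratios
(e.g. 648 µM over a 25 µM K_d ≈ 26-fold), and convert a mass
concentration to molarity given a monomer mass computed from a protein
sequence (Bio.SeqUtils average masses).

## Synthetic data (`synthio`)

The generator reproduces the statistical structure the analyses assume,
at desk scale:

- **Reference**: one 100 kb bee chromosome tiled by non-overlapping genes
  (protein-coding 55%, tRNA 25%, pre-miRNA 10%, other 10%;
  biotype-appropriate length ranges, 1–3 transcript lengths each)
  separated by 100–600 bp unannotated gaps, plus 10 kb viral references,
  each a single genome-spanning gene.
- **Libraries**: five samples mirroring the study design — three total-RJ
  and two MRJP-3-bound replicates — of 100 bp paired-end fragments with
  insert lengths ~ Normal(250, 40) truncated to [read length, 600]
  (typical TruSeq inserts; the source is silent on the distribution).
  Fragments longer than their source feature are truncated to it (tRNA
  genes are shorter than one read). Bee fragments are drawn from gene
  spans on the gene's sense strand or from gaps (on the plus strand — gaps
  define no sense, and a fixed strand keeps noise-free instances free of
  incidental duplexes); viral fragments come from both strands at a 3:1
  sense:antisense ratio. Mixing proportions get per-replicate logit-normal
  jitter (σ = 0.1) so replicate-level tests have genuine variance. The
  pull-down group is VDV-1-enriched (74.5% vs 49.5% in total RJ) —
  the planted effect the enrichment test must find in the bound fraction
  and must not find in total RJ, where bee and VDV-1 are balanced.
- **Planted duplexes**: pairs of distinct opposite-strand fragments of
  exactly one read length with a random offset bounded so that overlap
  ≥ 25 and overhangs ≤ 100 hold by construction; the ground-truth sidecar
  (including every fragment's true sense) is validated against these
  constraints before being returned. Ordinary mate pairs are emitted
  alongside and must never be called.
- **Titrations**: signal = baseline + Σ amplitude·θ + Gaussian noise with
  standard deviation `noise_sd` × dynamic range, triplicate, on a 16-step
  log-spaced prepared series (1 nM – 200 µM before 1:1 mixing);
  self-association curves saturate by ~40 µM added protein.
- **GO universe**: term sizes uniform in [5, 40); with length bias on, the
  probability of annotation grows with mean transcript length
  (weight ∝ length^γ). One extra term is planted truly enriched: 80% of
  its members come from a designated interest set capped at a third of the
  universe.

What the generator does **not** emulate: sequencing errors, PCR
duplicates, splicing, real viral or miRBase sequences, overlapping or
nested genes, and expression-level variation beyond the mixing jitter.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not robustness to alignment artifacts or annotation
complexity in real data.

## Problem sizes and determinism

Default test/pipeline scales — 100 kb + 2×10 kb references, 2 000–4 000
fragments per sample, 20 simulation seeds for the binding recoveries,
1 000 null terms for the GO calibration — were chosen as the smallest
sizes at which the statistical claims are meaningful. Every stochastic
path takes an explicit seed (`numpy.random.default_rng`); the full
pipeline under a fixed seed is byte-identical across runs, and the tests
assert this end to end.

## Known limitations

- The screen's fragment mode requires mate-merged input and does not
  attempt to rescue unpaired reads.
- The Wallenius approximation uses a single odds per term (mean weight in
  vs out), not per-gene weights; with extreme weight heterogeneity inside
  a term this is coarser than a full multivariate treatment.
- Phase-count selection by BIC assumes i.i.d. Gaussian residuals; strongly
  heteroscedastic titrations would need weighted fits.
- Amplitude degeneracy: phases closer than ~3-fold in K_d are not reliably
  separable at 16-point/1% designs; the 2-fold recovery criterion reflects
  this.
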