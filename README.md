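# jellyseq

Honeybee royal jelly (RJ) carries naturally occurring RNA, and the abundant
jelly protein MRJP-3 binds that RNA non-specifically, assembling
extracellular ribonucleoprotein granules that stabilize RNA and support its
transfer between bees. `jellyseq` re-implements the computational analyses
behind that biology as a tested, reusable Python package:

- **Putative dsRNA screen** — calls opposite-strand read overlaps in
  stranded RNA-seq: a duplex candidate is a pair of reads from two distinct
  molecules on opposite strands with an overlap of at least 25 nt and an
  overhang of at most 100 nt on either side. Candidates are deduplicated by
  their overlap coordinates, classified against the gene annotation
  (protein-coding / tRNA / pre-miRNA / unannotated), quantified per gene,
  and normalized with DESeq-style median-of-ratios size factors.
- **Composition & enrichment** — species and RNA-biotype composition of
  stranded libraries under dUTP chemistry, mean-ratio library-size
  normalization (sample total / mean total), a two-sided Welch two-sample
  *t* test for viral-vs-bee enrichment, and strand-specific per-base
  coverage with the log10(x+1) transform.
- **GO overrepresentation** — expressed-gene universe (count ≥ 2), terms
  with ≥ 5 annotated genes, Wallenius noncentral hypergeometric upper-tail
  p-values with a gene-length bias correction (monotone binned-isotonic
  weight function), flagged at raw p < 0.05.
- **MST binding analysis** — multiphasic microscale-thermophoresis binding
  curves modeled as a sum of independent 1:1 ligand-depletion isotherms

  θ(P; K_d, L) = ((P + L + K_d) − √((P + L + K_d)² − 4PL)) / (2L),

  fitted by multi-start least squares with the phase count selected by BIC,
  plus a Hill-type self-association model. Recovers a K_d ladder spanning
  nanomolar to tens of micromolar from noisy 16-step triplicate titrations.
- **Synthetic data** — a generator for every input the pipeline needs: a
  toy bee chromosome with biotyped genes and unannotated gaps, viral
  references (VDV-1-like) transcribed from both strands, stranded 100 bp
  paired-end fragments with planted opposite-strand duplex pairs and a
  ground-truth sidecar, noisy multiphasic titrations, and a gene→GO
  universe with controllable length bias. Everything is a pure function of
  (config, seed); no downloads required.

## Worked example

Run the full synthetic pipeline (simulate → screen → composition → GO →
binding fit):

```sh
jellyseq run-all --seed 5 --outdir demo --n-fragments 2000
```

Selected outputs from that exact run:

- `demo/composition/enrichment.tsv` — Welch test of bee vs VDV-1 normalized
  counts per fraction:

  ```
        group          t       df        p  significant
  mrjp3_bound -11.307253 1.999839 0.007733         True
     total_rj  -0.474654 3.994615 0.659818        False
  ```

  The simulated MRJP-3 pull-down is VDV-1-enriched (p < 0.05) while total
  RJ is balanced — the planted study condition, recovered by the test.

- `demo/screen/unique_duplexes.tsv` — 2010 unique duplex loci, all planted
  inside protein-coding genes in this configuration, each with its overlap
  interval, length, gene assignment, biotype class and candidate support.

- `demo/binding/binding_fit.json` — BIC selects 3 phases for the simulated
  ssRNA-style curve and recovers the K_d ladder:

  ```
  selected_phases: 3   (BIC −124.1 / −216.9 / −311.4 / −305.6 for 1..4)
  kds_molar: 3.19e-09, 3.35e-07, 3.22e-05
  ```

  against ground truth 4 nM / 300 nM / 25 µM — each within 2-fold, the
  resolution 16-point MST designs support for tight and weak phases.

Every stage is also available separately (`jellyseq simulate`,
`screen-dsrna`, `composition`, `go`, `fit-binding`); each writes a
JSON-lines manifest of its artifacts and refuses to overwrite without
`--force`.

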