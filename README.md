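# ntarseq

Detection, positional classification and strand-aware validation of
**novel transcriptionally active regions (nTARs)** from aligned RNA-seq
reads, together with the surrounding transcriptome descriptives: FPKM
quantification and presence calls, tissue-enhancement, gene-detection
saturation modelling and 5'→3' coverage-bias profiling.

The package is aimed at transcriptomics analysts who want the classic
two-protocol discovery design as a tested, reproducible pipeline:

1. **Screening pass** — an unstranded library's uniquely-mapped reads
   are piled into per-base coverage tracks; maximal covered runs that
   overlap *no* annotated exon (union of two annotation sources) and
   pass conservative thresholds (length ≥ 50 bp, mean depth ≥ 3,
   ≥ 5 reads, ≥ 2 independent start points) become nTAR candidates.
2. **Classification** — each candidate is placed into one of nine
   positional classes relative to condensed gene models
   (isoform-union "supertranscripts"), with priority
   ISE > ELD/ELU > UGI/DGI > IGE > UGN/DGN > NGA and up-/downstream
   always relative to the related gene's strand:

   | label | geometry |
   |-------|----------|
   | ISE | covers a whole intron |
   | ELU / ELD | intronic, flush with an exon's 5'/3' edge |
   | UGI / DGI | outside the gene, flush with its 5'/3' boundary |
   | IGE | intronic, touching no exon |
   | UGN / DGN | within 10 kb of the gene's 5'/3' side |
   | NGA | > 10 kb from every gene |

3. **Validation pass** — a strand-specific library confirms candidates
   (≥ 3 overlapping reads) and calls their orientation
   (sense/antisense vs. the related gene; mixed reads → ambiguous),
   yielding per-class sense:antisense ratios, detection ratios
   (nTAR coverage / related-gene coverage, binned at 0.25), poly-A
   3'-anchor confirmation, and gene-corrected cross-tissue fold
   changes at the penalized 3-fold rule `a/(b+1) ≥ 3`.

Gene-level statistics use the direct FPKM definition over the condensed
exon model, presence = FPKM > 0.01 with ≥ 2 distinct 5' start points,
and gene-detection saturation is modelled by random read drawing with
an iteratively-refit hyperbola `y = a·x/(b+x)` whose asymptote `a`
estimates the detectable gene count at unlimited depth.

A fully-specified synthetic genome generator plants all nine nTAR
classes with known orientation, expression and poly-A status, emulates
the unstranded protocol's 3' bias and the stranded protocol's uniform
coverage, and emits machine-readable truth tables — so the entire
pipeline is testable end to end without any external data.

## Worked example

```bash
ntarseq run --seed 1 --out runs/demo
```

simulates the default two-tissue study (2 chromosomes × 1.2 Mb,
40 genes, 27 planted nTARs, ~22k screening reads per tissue) and runs
every stage. It prints:

```
ntarseq run report
==================
screening reads used: tissueA=22644, tissueB=25493
present genes: tissueA=33, tissueB=30
present in both: 26; only tissueA: 7; only tissueB: 4; total present: 37
tissue-enhanced (shared present): tissueA=6, tissueB=7, total=13
nTARs tissueA: candidates=27, confirmed=27
  classes: DGI=3, DGN=3, ELD=3, ELU=3, IGE=3, ISE=3, NGA=3, UGI=3, UGN=3
nTARs tissueB: candidates=27, confirmed=27
  classes: DGI=3, DGN=3, ELD=3, ELU=3, IGE=3, ISE=3, NGA=3, UGI=3, UGN=3
saturation asymptote (detectable genes): 30.5
planted-truth recovery: 1.000 correct class; orientation accuracy 1.000
```

Reading this: 33 of 40 genes pass the presence call in tissue A (the
planted program makes ~10% of genes absent per tissue and some too rare
to detect); 26 are present in both tissues and 13 of those shared genes
differ ≥ 3-fold after the +1 penalty. All 27 planted nTARs are
detected, classified into their true class, confirmed by the stranded
protocol, and their orientation calls match the planted truth. The
saturation fit estimates ~30 genes detectable at unlimited depth,
consistent with the 37 genes carrying any expression. Per-candidate
tables (`ntars_<tissue>.tsv`/`.bed`), coverage bedGraphs and a JSON
report are written under `runs/demo/`.

Stage-wise subcommands (`simulate`, `condense`, `mask`, `coverage`,
`expression`, `ntar-detect`, `saturation`) operate on standard files
(GTF/BED12 annotation, BED6 or BAM alignments, bedGraph output) for use
with real data.

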