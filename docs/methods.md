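# Methods

This note documents the models and procedures ntarseq implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was open.

## Coordinate conventions and gene models

All coordinates are 0-based, half-open. GTF input (1-based, inclusive)
is converted on read; BED flavours are native. Isoforms sharing a gene
symbol are fused into a **condensed gene**: the union of all exons of
all isoforms, overlapping exons merged. Condensation conserves exonic
base coverage exactly (an invariant the test suite asserts per symbol).
A symbol occurring on more than one chromosome or strand is rejected by
default; a `disambiguate` flag suffixes such symbols with their locus
instead. The **exon mask** is the strand-ignored union of exon
intervals across *all* loaded annotation sources — strand-ignored
because the screening protocol is unstranded, so any annotated exonic
base disqualifies a position from being novel regardless of strand.

Nearest-gene distance is measured between the query and the condensed
gene's *span* boundaries (not the TSS), since the positional classes
are drawn relative to gene bodies. Ties between equidistant genes
resolve deterministically: smaller span start, then lexicographically
smaller symbol.

## Coverage, start points, and nTAR detection

Depth at a base counts reads whose aligned blocks contain it. An
**independent start point (SP)** is a distinct 5'-most alignment
coordinate among the reads overlapping a region (leftmost base of a
'+' read, rightmost of a '−' read); counting distinct SPs rather than
reads guards against clonal amplification artifacts. Spliced BAM
alignments contribute one depth block per aligned segment but a single
SP; soft-clipped bases never contribute. Reads overlapping a region by
≥ 1 bp count toward its read and SP tallies.

nTAR detection subtracts the exon mask from the covered-base set and
keeps maximal runs passing, each independently:

| parameter | default | meaning |
|---|---|---|
| `min_length` | 50 bp | minimum run length |
| `min_avg_cov` | 3 reads/bp | mean depth over the run |
| `min_reads` | 5 | overlapping screening reads |
| `min_sp` | 2 | distinct 5' start points |

Runs split by mask subtraction are separate candidates and are
filtered piecewise.

## Positional classification

Nine classes, priority ISE > ELD/ELU > UGI/DGI > IGE > UGN/DGN > NGA;
each candidate receives exactly one label. "Flush" contiguity is 0-gap
by default (a configurable tolerance exists): the covered run would
merge with the exon or gene boundary if the mask were removed. ISE
requires every base of some intron covered; partial intron coverage
falls through to ELU/ELD/IGE. Gene-internal classes bind to the
*enclosing* gene; neighbourhood classes (window 10 kb by default) to
the *closest* gene; conflicts resolve by class priority, then distance,
then gene order. Up/downstream is always relative to the related
gene's strand.

A useful symmetry, asserted over random genomes: mirroring the
coordinate axis (gene strands kept) swaps every U↔D label and
preserves NGA/IGE/ISE; mirroring *and* flipping strands — a true
reverse complement — changes no label, because both operations
together preserve gene-relative orientation.

## Validation, orientation, and downstream statistics

A candidate is **confirmed** by ≥ 3 overlapping strand-specific reads.
Orientation is called only when all supporting reads agree (sense =
same strand as the related gene); mixed support is `ambiguous`, and
NGA candidates — which have no reference strand — stay `undetermined`
with their genomic-strand counts retained. Per-class sense:antisense
ratios use unambiguous confirmed calls only; a zero antisense count is
reported as an infinite ratio.

The **detection ratio** is the candidate's mean per-base screening
depth over the related gene's mean exonic depth (mean depth, not FPKM,
so both sides share a scale without length-normalization artifacts),
binned at 0.25 boundaries; an unexpressed related gene yields the
special category "related gene not expressed".

**Differential nTARs** use directional penalized folds `x/(y+1)` for
both the candidate (mean depth per tissue) and the related gene (FPKM
per tissue); the candidate fold is divided by the gene fold per
direction and the call fires at ≥ 3 in either direction. Degenerate
gene folds are handled explicitly: a zero gene fold against a positive
candidate fold gives an infinite corrected fold (differential); 0/0
gives 1 (no signal). The reported `corrected_fold` is oriented
A-vs-B: ≥ 3 means up in tissue A, ≤ 1/3 up in tissue B. NGA candidates
are uncorrected.

**Poly-A confirmation** requires ≥ 1 tag whose 3'-most aligned base
falls inside the candidate; a tag merely overlapping with its anchor
outside does not count.

## Expression and presence

FPKM is computed directly over the condensed exon model: reads
overlapping ≥ 1 exonic base, per kilobase of exonic model, per million
mapped reads. No isoform deconvolution is attempted — the presence and
fold-change logic only needs gene-level values. Presence requires FPKM
strictly above 0.01 *and* ≥ 2 SPs (a highly covered region fed by one
clonal stack stays absent). Tissue enhancement is `a/(b+1) ≥ 3`; the
+1 pseudo-FPKM damps spurious folds of rare transcripts, and the two
directions can never both fire (asserted as a property).

## Saturation modelling

Reads are drawn uniformly without replacement in fixed increments; a
condensed gene is detected once ≥ 5 of its assigned reads have been
drawn (a read assigns to the gene with the largest exonic overlap).
The curve is monotone by construction and its final point is
independent of the drawing order. The default model is the hyperbola
`y = a·x/(b+x)` (an exponential `a·(1−e^(−x/b))` is selectable); after
a least-squares fit, the *second* sign change of the observed-minus-
fitted residual sequence is located and the fit repeats on the points
from that crossing onward, until the Pearson correlation of the
current fit reaches 0.99, no further crossing or improvement
(Δr < 1e−4) exists, fewer than 4 points remain, or 20 rounds elapse.
The asymptote `a` is the estimate of genes detectable at unlimited
depth. On noiseless hyperbolic data the asymptote is recovered to
numerical precision with zero extra rounds.

## The synthetic study

`SimulationConfig` defines the reference conditions: 2 chromosomes ×
1.2 Mb, 40 genes (1–3 isoforms, 2–6 exons, log-normal exon/intron
lengths, both strands, two of them forced above the 5 kb length class),
two annotation sources (the second omits 15% of transcripts, emulating
the non-identity of two gene databases), a per-tissue log-uniform
expression program spanning 4 decades (10⁻²–10²) with 10% of genes
absent per tissue, and 3 planted nTARs per class (length 80–300 bp,
12× mean depth, 85% sense, 20% differential at 5-fold, 50%
poly-adenylated). Protocols: *screening* is unstranded with an
exponential 3' retention bias (half-distance 2 kb) applied to
transcripts > 5 kb; *validation* is stranded and positionally uniform;
*polyA* emits 3'-anchored tags at transcript and planted-nTAR 3' ends.
Fragment counts are Poisson with mean ∝ expression × exonic length; a
low uniform background (2×10⁻⁵ reads/bp) and 2% flagged multi-mappers
exercise the filters. Everything is deterministic under a fixed seed,
to the byte in the emitted files.

Generator properties a reader should know:

- **Boundary anchoring.** Planted nTARs of the flush-contiguity
  classes (ISE, ELU/ELD, UGI/DGI) always include fragments anchored at
  their defining boundary, so the covered run reaches it exactly;
  under purely uniform sampling the 0-gap geometry would be lost at
  any realistic depth and those classes would be unplantable.
- **Contiguous alignments.** Gene fragments are sampled within single
  exons (junction-spanning fragments rejected), matching the core's
  contiguous-interval read model; spliced alignments are handled only
  by the BAM reader.
- **Independent nTAR depth.** Planted nTAR depth is fixed per tissue
  rather than co-varying with the related gene's expression, so all
  nine classes stay detectable across the 4-decade gene program. A
  consequence is that on synthetic data the gene-corrected
  differential statistic also fires when the *gene* changes between
  tissues over a flat nTAR; the intended behaviour of the statistic
  itself (a 5× nTAR excess over a flat gene is flagged, a perfectly
  co-varying pair is not) is verified directly at the operation level.

What passing the planted-truth tests does *not* show about real data:
the generator has no mapping errors, no splice junctions in the
screening library, no overlapping genes, and intergenic spacing
generous enough that planted classes are unambiguous; real genomes
violate all four, and the conservative thresholds (not the generator)
are what carries over.

## Problem sizes and numerics

The default test and acceptance runs use the 2 × 1.2 Mb / 40-gene
configuration (~20–25k screening reads per tissue) and, for the
brute-force oracle comparisons, a 1 × 100 kb / 5-gene configuration
with a proportionally scaled 3 kb neighbourhood window — sizes chosen
so per-base reference implementations remain exact and fast.
Percentages are rounded half-up at the printed decimal count. The
saturation fit uses bounded least squares (positive parameters) with
the observed maximum as the asymptote's starting value; degenerate
inputs (all-zero curves, < 4 points) are errors, not silent results.
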