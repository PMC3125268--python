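"""Synthetic transcriptome generator with planted ground truth.

Emulates the study design end-to-end without any external data: a small
genome with multi-isoform genes on both strands and two annotation
sources; an expression program per tissue spanning four orders of
magnitude; planted novel transcribed regions (nTARs) of all nine
positional classes with known orientation, tissue fold changes and
poly-A status; and already-aligned reads for three library protocols —

* screening: unstranded, with an exponential 3' retention bias on long
  transcripts (oligo-dT/template-switch emulation),
* validation: strand-specific, positionally uniform (RNA fragmentation
  emulation),
* polyA: single 3'-anchored tags at transcript/nTAR 3' ends.

Everything is deterministic under a fixed seed; truth tables are
machine-readable so every pipeline stage can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    CondensedGene,
    GenomeAnnotation,
    Interval,
    Transcript,
    condense_genes,
)
from .coverage import AlignedRead

_PROTO_ID = {"screening": 1, "validation": 2, "polyA": 3}
_CLASS_ID = {"genome": 0, "screening": 1, "validation": 2, "polyA": 3, "noise": 4}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults define the reference conditions."""

    n_chromosomes: int = 2
    chrom_length: int = 1_200_000
    n_genes: int = 40
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_gene: tuple[int, int] = (2, 6)
    # log-normal parameters (mean of log, sigma of log) with hard clips
    exon_length_logmean: float = 5.5  # exp(5.5) ~ 245 bp
    exon_length_logsd: float = 0.5
    exon_length_clip: tuple[int, int] = (80, 2500)
    intron_length_logmean: float = 6.7  # exp(6.7) ~ 810 bp
    intron_length_logsd: float = 0.6
    intron_length_clip: tuple[int, int] = (160, 3000)
    n_long_genes: int = 2  # genes forced above the 5 kb bias class boundary
    intergenic_gap: tuple[int, int] = (25_000, 40_000)
    # expression program
    tissues: tuple[str, str] = ("tissueA", "tissueB")
    fpkm_log10_range: tuple[float, float] = (-2.0, 2.0)  # >= 4 decades
    fraction_absent: float = 0.1  # per tissue, expression exactly 0
    depth_multiplier: float = 50.0  # expected gene reads per (FPKM unit x exonic kb)
    # planted nTARs
    ntars_per_class: int = 3
    ntar_length_range: tuple[int, int] = (80, 300)
    ntar_base_depth: float = 12.0  # mean per-base depth on planted nTARs
    ntar_validation_depth: float = 8.0
    sense_fraction: float = 0.85
    sense_fraction_per_class: dict = field(default_factory=dict)
    differential_fraction: float = 0.2
    differential_fold: float = 5.0
    polyA_fraction: float = 0.5
    neighbourhood_window: int = 10_000
    # protocols
    read_length: int = 35
    three_prime_bias_half_distance: float = 2000.0  # bp; 0 disables the bias
    bias_min_length: int = 5000  # bias applies to transcripts longer than this
    noise_read_rate: float = 2e-5  # random background reads per bp per run
    multimapper_fraction: float = 0.02  # extra reads flagged non-unique
    second_source_dropout: float = 0.15  # transcripts missing from the 2nd source
    seed: int = 0

    @property
    def margin(self) -> int:
        """Geometric safety margin around planted features (>= read length)."""
        return self.read_length + 5

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


@dataclass
class PlantedNtar:
    ntar_id: str
    interval: Interval  # strand field = true transcription strand
    ntar_class: str
    related_gene: str  # '.' for NGA
    orientation: str  # sense | antisense | na (NGA)
    depth: dict  # tissue -> planted mean screening depth
    differential: bool
    polyA: bool
    flush_left: bool = False  # covered run must reach interval.start exactly
    flush_right: bool = False


@dataclass
class GeneTruth:
    symbol: str
    expression: dict  # tissue -> planted FPKM-scale value (0 = absent)

    def present(self, tissue: str) -> bool:
        return self.expression[tissue] > 0


@dataclass
class TruthTable:
    genes: list[GeneTruth]
    ntars: list[PlantedNtar]

    def write_tsv(self, gene_path: str, ntar_path: str, tissues: tuple[str, str]) -> None:
        a, b = tissues
        with open(gene_path, "w") as fh:
            fh.write(f"symbol\texpr_{a}\texpr_{b}\tpresent_{a}\tpresent_{b}\n")
            for g in self.genes:
                fh.write(
                    f"{g.symbol}\t{g.expression[a]:.6g}\t{g.expression[b]:.6g}"
                    f"\t{int(g.present(a))}\t{int(g.present(b))}\n"
                )
        with open(ntar_path, "w") as fh:
            fh.write(
                f"ntar_id\tchrom\tstart\tend\tstrand\tclass\trelated_gene\torientation"
                f"\tdepth_{a}\tdepth_{b}\tdifferential\tpolyA\n"
            )
            for n in self.ntars:
                iv = n.interval
                fh.write(
                    f"{n.ntar_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{n.ntar_class}"
                    f"\t{n.related_gene}\t{n.orientation}\t{n.depth[a]:.3f}\t{n.depth[b]:.3f}"
                    f"\t{int(n.differential)}\t{int(n.polyA)}\n"
                )


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation  # condensed from the primary (full) source
    sources: dict  # source tag -> list[Transcript]
    truth: TruthTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genome and annotation


def _draw_lengths(rng, n, logmean, logsd, clip) -> np.ndarray:
    vals = np.exp(rng.normal(logmean, logsd, size=n))
    return np.clip(vals, clip[0], clip[1]).astype(int)


def _make_gene(rng, cfg: SimulationConfig, chrom: str, pos: int, symbol: str, long_gene: bool):
    strand = "+" if rng.random() < 0.5 else "-"
    if long_gene:
        n_exons = 3
        exon_lens = np.full(3, 2200)
    else:
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = _draw_lengths(
            rng, n_exons, cfg.exon_length_logmean, cfg.exon_length_logsd, cfg.exon_length_clip
        )
    intron_lens = _draw_lengths(
        rng, max(n_exons - 1, 0), cfg.intron_length_logmean, cfg.intron_length_logsd,
        cfg.intron_length_clip,
    )
    exons = []
    p = pos
    for i in range(n_exons):
        exons.append(Interval(chrom, p, p + int(exon_lens[i]), strand))
        p += int(exon_lens[i])
        if i < n_exons - 1:
            p += int(intron_lens[i])
    return symbol, exons, p  # p = gene span end


def _make_isoforms(rng, cfg: SimulationConfig, symbol: str, exons: list[Interval]) -> list[Transcript]:
    lo, hi = cfg.isoforms_per_gene
    n_iso = int(rng.integers(lo, hi + 1))
    out = [Transcript(f"{symbol}.1", symbol, list(exons), "src1")]
    for k in range(2, n_iso + 1):
        if len(exons) < 2:
            break
        i = int(rng.integers(0, len(exons) - 1))
        j = int(rng.integers(i + 1, len(exons) + 1))
        out.append(Transcript(f"{symbol}.{k}", symbol, list(exons[i:j]), "src1"))
    return out


def simulate_genome(config: SimulationConfig, seed: int | None = None) -> SimulatedGenome:
    """Build the genome: genes, two annotation sources, planted nTARs, truth."""
    cfg = config
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, _CLASS_ID["genome"]])
    genes_per_chrom = cfg.n_genes // cfg.n_chromosomes
    leftovers = cfg.n_genes - genes_per_chrom * cfg.n_chromosomes
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)}
    gene_models: list[tuple[str, list[Interval]]] = []  # (symbol, exons)
    gaps: list[tuple[str, int, int, str | None, str | None]] = []  # chrom, start, end, left sym, right sym
    gi = 0
    n_long_left = cfg.n_long_genes
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        n_here = genes_per_chrom + (1 if ci < leftovers else 0)
        pos = int(rng.integers(*cfg.intergenic_gap))
        prev_sym: str | None = None
        prev_end = 0
        for _ in range(n_here):
            symbol = f"gene{gi:03d}"
            long_gene = n_long_left > 0
            if long_gene:
                n_long_left -= 1
            sym, exons, end = _make_gene(rng, cfg, chrom, pos, symbol, long_gene)
            if end > cfg.chrom_length - cfg.intergenic_gap[0]:
                raise SimulationError(
                    f"infeasible packing: {cfg.n_genes} genes do not fit in "
                    f"{cfg.n_chromosomes} x {cfg.chrom_length} bp"
                )
            gaps.append((chrom, prev_end, pos, prev_sym, symbol))
            gene_models.append((sym, exons))
            prev_sym, prev_end = symbol, end
            pos = end + int(rng.integers(*cfg.intergenic_gap))
            gi += 1
        gaps.append((chrom, prev_end, cfg.chrom_length, prev_sym, None))

    # isoforms and the two annotation sources
    src1: list[Transcript] = []
    for sym, exons in gene_models:
        src1.extend(_make_isoforms(rng, cfg, sym, exons))
    src2 = [
        Transcript(t.id, t.gene_symbol, list(t.exons), "src2")
        for t in src1
        if rng.random() >= cfg.second_source_dropout
    ]
    condensed = condense_genes(src1)
    annotation = GenomeAnnotation(src1, condensed, chrom_sizes)

    # expression program
    lo, hi = cfg.fpkm_log10_range
    gene_truth = []
    for sym, _ in gene_models:
        expr = {}
        for tissue in cfg.tissues:
            if rng.random() < cfg.fraction_absent:
                expr[tissue] = 0.0
            else:
                expr[tissue] = float(10 ** rng.uniform(lo, hi))
        gene_truth.append(GeneTruth(sym, expr))

    ntars = _plant_ntars(rng, cfg, condensed, gaps)
    truth = TruthTable(gene_truth, ntars)
    return SimulatedGenome(annotation, {"src1": src1, "src2": src2}, truth, cfg)


def _ntar_tissue_depths(rng, cfg: SimulationConfig) -> tuple[dict, bool]:
    differential = rng.random() < cfg.differential_fraction
    a, b = cfg.tissues
    base = cfg.ntar_base_depth
    if differential:
        up = a if rng.random() < 0.5 else b
        depth = {a: base * cfg.differential_fold if up == a else base,
                 b: base * cfg.differential_fold if up == b else base}
    else:
        depth = {a: base, b: base}
    return depth, differential


def _plant_ntars(rng, cfg: SimulationConfig, condensed: list[CondensedGene], gaps) -> list[PlantedNtar]:
    margin = cfg.margin
    lmin, lmax = cfg.ntar_length_range
    by_symbol = {g.gene_symbol: g for g in condensed}

    # pools of intronic slots (gene, intron index), one planted nTAR per intron
    intron_pool: list[tuple[CondensedGene, int]] = []
    for g in condensed:
        for i, intron in enumerate(g.introns):
            intron_pool.append((g, i))
    intron_pool = [intron_pool[i] for i in rng.permutation(len(intron_pool))]
    gap_pool = [gaps[i] for i in rng.permutation(len(gaps))]

    ntars: list[PlantedNtar] = []
    counter = 0

    def _take_intron(min_len: int, max_len: int | None = None):
        for idx, (g, i) in enumerate(intron_pool):
            intron = g.introns[i]
            if len(intron) >= min_len and (max_len is None or len(intron) <= max_len):
                intron_pool.pop(idx)
                return g, intron
        raise SimulationError("infeasible planting: no suitable intron left")

    def _take_gap(min_span: int, need_left: bool = False, need_right: bool = False):
        for idx, (chrom, s, e, left_sym, right_sym) in enumerate(gap_pool):
            if e - s < min_span:
                continue
            if need_left and left_sym is None:
                continue
            if need_right and right_sym is None:
                continue
            gap_pool.pop(idx)
            return chrom, s, e, left_sym, right_sym
        raise SimulationError("infeasible planting: no suitable intergenic gap left")

    def _take_gap_site(min_span: int, want_five: bool):
        """A gap plus the flanking gene whose gap-facing end is the wanted gene end.

        The left gene faces the gap with its right (genomic) end, which is its
        5' end iff it lies on '-'; the right gene faces with its left end,
        its 5' end iff it lies on '+'.
        """
        for idx, (chrom, s, e, left_sym, right_sym) in enumerate(gap_pool):
            if e - s < min_span:
                continue
            options = []
            if right_sym is not None and (by_symbol[right_sym].strand == "+") == want_five:
                options.append(("right", right_sym))
            if left_sym is not None and (by_symbol[left_sym].strand == "-") == want_five:
                options.append(("left", left_sym))
            if not options:
                continue
            side, sym = options[int(rng.integers(0, len(options)))]
            gap_pool.pop(idx)
            return chrom, s, e, side, by_symbol[sym]
        raise SimulationError("infeasible planting: no gap with a suitably oriented gene")

    def _orientation(label: str, gene: CondensedGene | None):
        if gene is None:
            strand = "+" if rng.random() < 0.5 else "-"
            return strand, "na"
        p_sense = cfg.sense_fraction_per_class.get(label, cfg.sense_fraction)
        if rng.random() < p_sense:
            return gene.strand, "sense"
        return ("-" if gene.strand == "+" else "+"), "antisense"

    def _add(label, chrom, start, end, gene, flush_left=False, flush_right=False):
        nonlocal counter
        strand, orient = _orientation(label, gene)
        depth, differential = _ntar_tissue_depths(rng, cfg)
        ntars.append(
            PlantedNtar(
                ntar_id=f"ntar{counter:03d}",
                interval=Interval(chrom, int(start), int(end), strand),
                ntar_class=label,
                related_gene=gene.gene_symbol if gene else ".",
                orientation=orient,
                depth=depth,
                differential=differential,
                polyA=rng.random() < cfg.polyA_fraction,
                flush_left=flush_left,
                flush_right=flush_right,
            )
        )
        counter += 1

    for _ in range(cfg.ntars_per_class):
        # ISE: the nTAR is a whole intron (both ends flush with exons)
        g, intron = _take_intron(max(lmin, 60), 700)
        _add("ISE", g.chrom, intron.start, intron.end, g, flush_left=True, flush_right=True)

    for label in ("ELU", "ELD"):
        for _ in range(cfg.ntars_per_class):
            length = int(rng.integers(lmin, lmax + 1))
            g, intron = _take_intron(length + margin + 10)
            # ELU touches an exon's 5' edge, ELD its 3' edge (gene-strand relative)
            at_exon_left_edge = (label == "ELU") == (g.strand == "+")
            if at_exon_left_edge:
                start, end = intron.end - length, intron.end
                _add(label, g.chrom, start, end, g, flush_right=True)
            else:
                start, end = intron.start, intron.start + length
                _add(label, g.chrom, start, end, g, flush_left=True)

    for _ in range(cfg.ntars_per_class):
        # IGE: strictly interior to an intron, margin to both exons
        length = int(rng.integers(lmin, lmax + 1))
        g, intron = _take_intron(length + 2 * margin + 10)
        lo_s = intron.start + margin
        hi_s = intron.end - margin - length
        start = int(rng.integers(lo_s, hi_s + 1))
        _add("IGE", g.chrom, start, start + length, g)

    for label in ("UGI", "DGI"):
        for _ in range(cfg.ntars_per_class):
            length = int(rng.integers(lmin, lmax + 1))
            # flush against the 5' end of a gene for UGI, the 3' end for DGI
            chrom, s, e, side, g = _take_gap_site(length + 2 * margin, label == "UGI")
            if side == "right":
                _add(label, chrom, g.span.start - length, g.span.start, g, flush_right=True)
            else:
                _add(label, chrom, g.span.end, g.span.end + length, g, flush_left=True)

    for label in ("UGN", "DGN"):
        for _ in range(cfg.ntars_per_class):
            length = int(rng.integers(lmin, lmax + 1))
            # distance kept well inside the window so detection-side shrinkage
            # of the covered run cannot push the region out of the class
            dist = int(rng.integers(500, int(0.8 * cfg.neighbourhood_window)))
            chrom, s, e, side, g = _take_gap_site(
                dist + length + cfg.neighbourhood_window + 2 * margin, label == "UGN"
            )
            if side == "right":
                end = g.span.start - dist
                start = end - length
            else:
                start = g.span.end + dist
                end = start + length
            _add(label, chrom, start, end, g)

    window = cfg.neighbourhood_window
    for _ in range(cfg.ntars_per_class):
        length = int(rng.integers(lmin, lmax + 1))
        need = 2 * (window + margin) + length
        chrom, s, e, left_sym, right_sym = _take_gap(need)
        lo_s = s + (window + margin if left_sym else margin)
        hi_s = e - (window + margin if right_sym else margin) - length
        start = int(rng.integers(lo_s, hi_s + 1))
        _add("NGA", chrom, start, start + length, None)

    return ntars


# ---------------------------------------------------------------------------
# reads


def _transcript_layout(gene: CondensedGene) -> tuple[np.ndarray, np.ndarray, int]:
    """(exon starts, cumulative exonic offsets, exonic length) for position math."""
    starts = np.array([e.start for e in gene.exons], dtype=np.int64)
    lens = np.array([len(e) for e in gene.exons], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(lens)[:-1]))
    return starts, offsets, int(lens.sum())


def _gene_fragments(rng, gene: CondensedGene, n: int, read_length: int) -> np.ndarray:
    """Genomic start positions of n fragments, each inside a single exon."""
    weights = np.array([max(len(e) - read_length + 1, 0) for e in gene.exons], dtype=float)
    total = weights.sum()
    if total == 0 or n == 0:
        return np.empty(0, dtype=np.int64)
    probs = weights / total
    exon_idx = rng.choice(len(gene.exons), size=n, p=probs)
    out = np.empty(n, dtype=np.int64)
    for i, ei in enumerate(exon_idx):
        e = gene.exons[ei]
        out[i] = rng.integers(e.start, e.end - read_length + 1)
    return out


def _three_prime_retention(
    positions: np.ndarray, gene: CondensedGene, read_length: int, half_distance: float
) -> np.ndarray:
    """Retention probability per fragment from its distance to the 3' end."""
    starts, offsets, exonic_len = _transcript_layout(gene)
    exon_of = np.searchsorted(starts, positions, side="right") - 1
    tx_coord = offsets[exon_of] + (positions - starts[exon_of])  # 5'->3' on '+' genes
    if gene.strand == "+":
        dist3 = exonic_len - (tx_coord + read_length)
    else:
        dist3 = tx_coord
    dist3 = np.maximum(dist3, 0)
    return np.exp2(-dist3 / half_distance)


def simulate_reads(
    genome: SimulatedGenome, protocol: str, tissue: str, seed: int | None = None
) -> list[AlignedRead]:
    """Sample already-aligned reads for one protocol and tissue.

    Fragment counts are Poisson with mean proportional to planted
    expression x exonic length; the screening protocol thins fragments of
    long transcripts by the exponential 3' retention curve and assigns
    random strands (unstranded library).
    """
    cfg = genome.config
    if protocol not in _PROTO_ID:
        raise SimulationError(f"unknown protocol {protocol!r}")
    seed = cfg.seed if seed is None else seed
    tissue_id = list(cfg.tissues).index(tissue)
    rng = np.random.default_rng([seed, _PROTO_ID[protocol], tissue_id])
    rl = cfg.read_length
    by_symbol = {g.gene_symbol: g for g in genome.annotation.condensed}
    truth_by_symbol = {g.symbol: g for g in genome.truth.genes}
    reads: list[AlignedRead] = []

    if protocol == "polyA":
        reads.extend(_polyA_tags(rng, genome, tissue, rl))
        return reads

    # gene fragments
    for g in genome.annotation.condensed:
        expr = truth_by_symbol[g.gene_symbol].expression[tissue]
        if expr == 0:
            continue
        rate = expr * (g.exonic_length / 1000.0) * cfg.depth_multiplier
        n = int(rng.poisson(rate))
        pos = _gene_fragments(rng, g, n, rl)
        if protocol == "screening" and cfg.three_prime_bias_half_distance > 0 and \
                g.exonic_length > cfg.bias_min_length and len(pos):
            keep = rng.random(len(pos)) < _three_prime_retention(
                pos, g, rl, cfg.three_prime_bias_half_distance
            )
            pos = pos[keep]
        for p in pos:
            strand = (("+", "-")[rng.integers(0, 2)] if protocol == "screening" else g.strand)
            reads.append(AlignedRead(g.chrom, int(p), int(p) + rl, strand, protocol))

    # planted nTAR fragments
    for n_t in genome.truth.ntars:
        iv = n_t.interval
        depth = n_t.depth[tissue] if protocol == "screening" else (
            cfg.ntar_validation_depth * n_t.depth[tissue] / cfg.ntar_base_depth
        )
        n = int(rng.poisson(depth * len(iv) / rl))
        starts = rng.integers(iv.start, iv.end - rl + 1, size=n)
        if protocol == "screening":
            # boundary-flush classes get end-anchored fragments so the covered
            # run reaches the defining boundary exactly
            anchors = []
            if n_t.flush_left:
                anchors.append(iv.start)
            if n_t.flush_right:
                anchors.append(iv.end - rl)
            if anchors:
                starts = np.concatenate((starts, np.array(anchors, dtype=starts.dtype)))
        for p in starts:
            strand = (("+", "-")[rng.integers(0, 2)] if protocol == "screening" else iv.strand)
            reads.append(AlignedRead(iv.chrom, int(p), int(p) + rl, strand, protocol))

    # background noise and multi-mappers
    genome_bp = sum(genome.annotation.chrom_sizes.values())
    n_noise = int(rng.poisson(cfg.noise_read_rate * genome_bp))
    reads.extend(_random_reads(rng, genome, n_noise, rl, protocol, unique=True))
    n_multi = int(round(cfg.multimapper_fraction * len(reads)))
    reads.extend(_random_reads(rng, genome, n_multi, rl, protocol, unique=False))
    return reads


def _random_reads(rng, genome, n, rl, protocol, unique) -> list[AlignedRead]:
    out = []
    chroms = sorted(genome.annotation.chrom_sizes)
    sizes = np.array([genome.annotation.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(n):
        ci = int(rng.choice(len(chroms), p=probs))
        p = int(rng.integers(0, sizes[ci] - rl))
        strand = ("+", "-")[rng.integers(0, 2)]
        out.append(AlignedRead(chroms[ci], p, p + rl, strand, protocol, unique=unique))
    return out


def _polyA_tags(rng, genome: SimulatedGenome, tissue: str, rl: int) -> list[AlignedRead]:
    """3'-anchored tags at gene ends and at poly-A planted nTAR 3' ends."""
    out = []
    truth_by_symbol = {g.symbol: g for g in genome.truth.genes}
    for g in genome.annotation.condensed:
        if truth_by_symbol[g.gene_symbol].expression[tissue] == 0:
            continue
        k = int(rng.poisson(1.0))
        for _ in range(k):
            out.append(_anchored_tag(g.chrom, g.span, g.strand, rl))
    for n_t in genome.truth.ntars:
        if not n_t.polyA:
            continue
        k = 1 + int(rng.poisson(0.5))
        for _ in range(k):
            out.append(_anchored_tag(n_t.interval.chrom, n_t.interval, n_t.interval.strand, rl))
    return out


def _anchored_tag(chrom: str, span: Interval, strand: str, rl: int) -> AlignedRead:
    if strand == "+":
        return AlignedRead(chrom, span.end - rl, span.end, "+", "polyA_tag")
    return AlignedRead(chrom, span.start, span.start + rl, "-", "polyA_tag")


# ---------------------------------------------------------------------------
# file emission


def write_run(genome: SimulatedGenome, outdir: str) -> dict:
    """Emit annotation (GTF + BED12, two sources), reads, tags, truth and config.

    Returns a manifest of written paths.
    """
    import os

    from .annotation import write_bed12
    from .coverage import write_bed6

    os.makedirs(outdir, exist_ok=True)
    cfg = genome.config
    manifest: dict[str, str] = {}

    for tag, transcripts in genome.sources.items():
        gtf = os.path.join(outdir, f"annotation_{tag}.gtf")
        bed = os.path.join(outdir, f"annotation_{tag}.bed12")
        _write_gtf(transcripts, gtf)
        write_bed12(transcripts, bed)
        manifest[f"gtf_{tag}"] = gtf
        manifest[f"bed12_{tag}"] = bed

    sizes = os.path.join(outdir, "chrom.sizes")
    with open(sizes, "w") as fh:
        for chrom in sorted(genome.annotation.chrom_sizes):
            fh.write(f"{chrom}\t{genome.annotation.chrom_sizes[chrom]}\n")
    manifest["chrom_sizes"] = sizes

    for tissue in cfg.tissues:
        for protocol in ("screening", "validation", "polyA"):
            reads = simulate_reads(genome, protocol, tissue)
            path = os.path.join(outdir, f"reads_{protocol}_{tissue}.bed6")
            write_bed6(reads, path)
            manifest[f"reads_{protocol}_{tissue}"] = path

    gene_truth = os.path.join(outdir, "truth_genes.tsv")
    ntar_truth = os.path.join(outdir, "truth_ntars.tsv")
    genome.truth.write_tsv(gene_truth, ntar_truth, cfg.tissues)
    manifest["truth_genes"] = gene_truth
    manifest["truth_ntars"] = ntar_truth

    cfg_path = os.path.join(outdir, "config.json")
    cfg.to_json(cfg_path)
    manifest["config"] = cfg_path
    return manifest


def _write_gtf(transcripts: list[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                attrs = f'gene_id "{t.gene_symbol}"; transcript_id "{t.id}";'
                fh.write(
                    f"{e.chrom}\tntarseq_sim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )
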