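"""Gene annotation models: loading, isoform condensation, exon masks, nearest-gene queries.

All coordinates are 0-based half-open internally.  GTF input (1-based,
end-inclusive) is converted on read; BED flavours are native.  Transcript
isoforms sharing a gene symbol are fused into a single "condensed gene"
(the union of all exons of all isoforms, overlaps merged), the unit at
which presence, saturation and novel-region adjacency are evaluated.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class AnnotationError(ValueError):
    """Raised for malformed annotation input or inconsistent gene models."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass
class Transcript:
    """One annotated isoform: an ordered list of disjoint exons on one strand."""

    id: str
    gene_symbol: str
    exons: list[Interval]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(f"transcript {self.id} spans multiple chromosomes/strands")
        self.exons = merge_intervals(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class CondensedGene:
    """Union of all exons of all isoforms sharing a gene symbol ("supertranscript")."""

    gene_symbol: str
    exons: list[Interval]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(Interval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GenomicMask:
    """Per chromosome, disjoint sorted intervals covering every annotated exonic base.

    Strand-ignored: the screening protocol is unstranded, so any annotated
    exonic base disqualifies a position from being novel regardless of strand.
    """

    intervals: dict[str, list[Interval]] = field(default_factory=dict)

    def masked_bases(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return sum(len(iv) for iv in self.intervals.get(chrom, []))
        return sum(len(iv) for ivs in self.intervals.values() for iv in ivs)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for fast searchsorted queries."""
        ivs = self.intervals.get(chrom, [])
        return (
            np.fromiter((iv.start for iv in ivs), dtype=np.int64, count=len(ivs)),
            np.fromiter((iv.end for iv in ivs), dtype=np.int64, count=len(ivs)),
        )

    def overlap_bases(self, query: Interval) -> int:
        """Number of masked bases inside ``query``."""
        total = 0
        for iv in self.intervals.get(query.chrom, []):
            if iv.start >= query.end:
                break
            lo, hi = max(iv.start, query.start), min(iv.end, query.end)
            if lo < hi:
                total += hi - lo
        return total


@dataclass
class GenomeAnnotation:
    """Loaded transcripts plus derived condensed gene models and chromosome sizes."""

    transcripts: list[Transcript]
    condensed: list[CondensedGene]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            size = self.chrom_sizes.get(t.chrom)
            if size is not None and t.span.end > size:
                raise AnnotationError(
                    f"transcript {t.id} extends past end of {t.chrom} ({t.span.end} > {size})"
                )
        self._by_chrom: dict[str, list[CondensedGene]] = {}
        for g in self.condensed:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for genes in self._by_chrom.values():
            genes.sort(key=lambda g: (g.span.start, g.span.end, g.gene_symbol))

    def genes_on(self, chrom: str) -> list[CondensedGene]:
        return self._by_chrom.get(chrom, [])


# ---------------------------------------------------------------------------
# interval primitives


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint list."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                prev = out.pop()
                out.append(Interval(prev.chrom, prev.start, iv.end, prev.strand))
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# loading


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def load_annotation(path: str, format: str, source: str = "") -> list[Transcript]:
    """Load transcripts from a GTF or BED12 file.

    GTF exon records are grouped by ``transcript_id``; 1-based inclusive
    coordinates become 0-based half-open.  BED12 block offsets are resolved
    against ``chromStart``.  Malformed records raise
    :class:`AnnotationError` naming the offending line.
    """
    if format == "gtf":
        return _load_gtf(path, source)
    if format == "bed12":
        return _load_bed12(path, source)
    raise AnnotationError(f"unknown annotation format {format!r}")


def _load_gtf(path: str, source: str) -> list[Transcript]:
    exons: dict[str, list[Interval]] = {}
    symbols: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinate") from exc
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: missing transcript_id attribute")
            sym = a.get("gene_name") or a.get("gene_id") or tid
            if tid not in exons:
                exons[tid] = []
                symbols[tid] = sym
                order.append(tid)
            exons[tid].append(Interval(chrom, s, e, strand))
    return [Transcript(tid, symbols[tid], exons[tid], source) for tid in order]


def _load_bed12(path: str, source: str) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
            if strand not in ("+", "-"):
                raise AnnotationError(f"{path}:{lineno}: unknown strand {strand!r}")
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(f"{path}:{lineno}: blockCount does not match block lists")
            symbol, _, tid = name.partition("|")
            exons = [
                Interval(chrom, start + off, start + off + size, strand)
                for size, off in zip(sizes, offsets)
            ]
            out.append(Transcript(tid or name, symbol, exons, source))
    return out


def write_bed12(genes: Sequence[CondensedGene | Transcript], path: str) -> None:
    """Write gene models as BED12 (name = gene symbol, or symbol|transcript id)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons
            span = g.span
            if isinstance(g, CondensedGene):
                name = g.gene_symbol
            else:
                name = f"{g.gene_symbol}|{g.id}"
            sizes = ",".join(str(len(e)) for e in exons)
            offsets = ",".join(str(e.start - span.start) for e in exons)
            fh.write(
                f"{span.chrom}\t{span.start}\t{span.end}\t{name}\t0\t{g.strand}"
                f"\t{span.start}\t{span.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def write_bed3(mask: GenomicMask, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(mask.intervals):
            for iv in mask.intervals[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# condensation / masking / nearest-gene


def condense_genes(
    transcripts: Sequence[Transcript], disambiguate: bool = False
) -> list[CondensedGene]:
    """Fuse isoforms sharing a gene symbol into one condensed gene.

    A symbol appearing on more than one chromosome or strand is an error
    unless ``disambiguate`` is set, in which case the symbol is suffixed
    with its chromosome and strand.
    """
    groups: dict[str, list[Transcript]] = {}
    for t in transcripts:
        groups.setdefault(t.gene_symbol, []).append(t)
    out = []
    for symbol in groups:
        by_locus: dict[tuple[str, str], list[Transcript]] = {}
        for t in groups[symbol]:
            by_locus.setdefault((t.chrom, t.strand), []).append(t)
        if len(by_locus) > 1 and not disambiguate:
            loci = ", ".join(f"{c}{s}" for c, s in sorted(by_locus))
            raise AnnotationError(f"gene symbol {symbol!r} occurs on multiple loci: {loci}")
        for (chrom, strand), ts in sorted(by_locus.items()):
            name = symbol if len(by_locus) == 1 else f"{symbol}_{chrom}{strand}"
            exons = merge_intervals(e for t in ts for e in t.exons)
            out.append(CondensedGene(name, exons))
    out.sort(key=lambda g: (g.chrom, g.span.start, g.gene_symbol))
    return out


def build_exon_mask(
    *annotations: Sequence[Transcript], chrom_sizes: dict[str, int] | None = None
) -> GenomicMask:
    """Union of all exon intervals across all annotation sources, strand-ignored."""
    per_chrom: dict[str, list[Interval]] = {}
    for transcripts in annotations:
        for t in transcripts:
            for e in t.exons:
                if chrom_sizes is not None:
                    size = chrom_sizes.get(e.chrom)
                    if size is None:
                        raise AnnotationError(f"exon on unknown chromosome {e.chrom}")
                    if e.end > size:
                        raise AnnotationError(
                            f"exon {e.chrom}:{e.start}-{e.end} beyond chromosome end {size}"
                        )
                per_chrom.setdefault(e.chrom, []).append(
                    Interval(e.chrom, e.start, e.end, ".")
                )
    return GenomicMask({chrom: merge_intervals(ivs) for chrom, ivs in per_chrom.items()})


def nearest_gene(
    query: Interval, condensed: Sequence[CondensedGene]
) -> tuple[CondensedGene | None, int, str]:
    """Closest condensed gene to ``query`` by span-boundary distance.

    Returns ``(gene, distance, side)`` where distance is 0 for overlap and
    side is relative to the *gene's* strand (upstream = toward the gene's
    5' end).  Ties resolve to the gene with the smaller span start, then
    the lexicographically smaller symbol.  ``(None, -1, 'none')`` if the
    query's chromosome carries no gene.
    """
    genes = [g for g in condensed if g.chrom == query.chrom]
    if not genes:
        return None, -1, "none"
    best: tuple[int, int, str, CondensedGene] | None = None
    for g in genes:
        span = g.span
        if span.start < query.end and query.start < span.end:
            dist = 0
        elif query.end <= span.start:
            dist = span.start - query.end
        else:
            dist = query.start - span.end
        key = (dist, span.start, g.gene_symbol, g)
        if best is None or key[:3] < best[:3]:
            best = key
    dist, _, _, gene = best
    span = gene.span
    if span.start < query.end and query.start < span.end:
        side = "overlapping"
    else:
        # flush (gap 0) still has a definite side
        query_is_left = query.end <= span.start
        if gene.strand == "+":
            side = "upstream" if query_is_left else "downstream"
        else:
            side = "downstream" if query_is_left else "upstream"
    return gene, dist, side


def sorted_spans(genes: Sequence[CondensedGene]) -> tuple[np.ndarray, np.ndarray, list[CondensedGene]]:
    """Genes sorted by span start with parallel start/end arrays (query helper)."""
    order = sorted(genes, key=lambda g: (g.span.start, g.span.end, g.gene_symbol))
    starts = np.array([g.span.start for g in order], dtype=np.int64)
    ends = np.array([g.span.end for g in order], dtype=np.int64)
    return starts, ends, order


def genes_near(
    query: Interval, genes: Sequence[CondensedGene], window: int
) -> list[CondensedGene]:
    """Genes whose span lies within ``window`` bp of (or overlaps) the query."""
    out = []
    for g in genes:
        if g.chrom != query.chrom:
            continue
        span = g.span
        if span.start - window <= query.end and query.start - window <= span.end:
            out.append(g)
    return out
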