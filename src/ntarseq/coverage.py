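"""Per-base coverage tracks, start-point sets and covered segments from unique alignments.

Reads arrive as contiguous genomic intervals (BED6) or as BAM records;
spliced BAM alignments contribute one depth block per aligned segment but
a single 5' start point.  A "start point" (SP) is a distinct 5'-most
alignment coordinate; counting distinct SPs rather than reads guards
against clonal amplification artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import Interval


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely-mapped read: contiguous blocks on one chromosome and strand."""

    chrom: str
    start: int
    end: int
    strand: str
    protocol: str = "screening"
    unique: bool = True
    # extra aligned blocks (spliced BAM reads); (start, end) pairs beyond the first
    blocks: tuple[tuple[int, int], ...] = ()

    @property
    def five_prime(self) -> int:
        """5'-most genomic coordinate (leftmost base for '+', rightmost for '-')."""
        if self.strand == "-":
            last_end = self.blocks[-1][1] if self.blocks else self.end
            return last_end - 1
        return self.start

    @property
    def interval(self) -> Interval:
        last_end = self.blocks[-1][1] if self.blocks else self.end
        return Interval(self.chrom, self.start, last_end, self.strand if self.strand in "+-" else ".")

    def all_blocks(self) -> list[tuple[int, int]]:
        return [(self.start, self.end), *self.blocks]


def load_alignments(
    path: str, format: str = "bed6", protocol: str = "screening", unique_only: bool = True
) -> list[AlignedRead]:
    """Load aligned reads from BED6 or BAM, optionally dropping multi-mappers.

    BED6 convention: score > 0 marks a uniquely-mapped read, score 0 a
    multi-mapper.  BAM: secondary/supplementary records, MAPQ 0 and NH > 1
    count as non-unique.  Soft-clipped bases never contribute to depth.
    """
    if format == "bed6":
        reads = _load_bed6(path, protocol)
    elif format == "bam":
        reads = _load_bam(path, protocol)
    else:
        raise CoverageError(f"unknown alignment format {format!r}")
    if unique_only:
        kept = [r for r in reads if r.unique]
    else:
        kept = reads
    if not kept:
        warnings.warn(f"{path}: no usable alignments", stacklevel=2)
    return kept


def _load_bed6(path: str, protocol: str) -> list[AlignedRead]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise CoverageError(f"{path}:{lineno}: expected 6 BED fields, got {len(fields)}")
            chrom, start, end, _name, score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise CoverageError(f"{path}:{lineno}: unknown strand {strand!r}")
            out.append(
                AlignedRead(chrom, int(start), int(end), strand, protocol, unique=float(score) > 0)
            )
    return out


def _load_bam(path: str, protocol: str) -> list[AlignedRead]:
    import pysam

    out = []
    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            unique = not (rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0)
            if unique and rec.has_tag("NH") and rec.get_tag("NH") > 1:
                unique = False
            blocks = rec.get_blocks()  # reference-consumed blocks, soft clips excluded
            if not blocks:
                continue
            merged = [list(blocks[0])]
            for s, e in blocks[1:]:
                if s <= merged[-1][1]:  # adjacent M/D ops
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            strand = "-" if rec.is_reverse else "+"
            first = merged[0]
            out.append(
                AlignedRead(
                    rec.reference_name,
                    first[0],
                    first[1],
                    strand,
                    protocol,
                    unique=unique,
                    blocks=tuple((s, e) for s, e in (tuple(b) for b in merged[1:])),
                )
            )
    return out


def write_bed6(reads: list[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            score = 50 if r.unique else 0
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t{score}\t{r.strand}\n")


@dataclass
class CoverageTrack:
    """Per-base read depth plus 5' start-point positions, optionally per strand."""

    chrom_sizes: dict[str, int]
    stranded: bool = False
    depth: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    # (chrom, strand) -> {5' coordinate: multiplicity}; strand '.' when unstranded
    start_points: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)
    total_mapped_reads: int = 0
    # sorted read interval arrays per (chrom, strand) for fast region counting
    _read_starts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    _read_ends: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    _read_fps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def _keys(self, chrom: str, strand: str = "any") -> list[tuple[str, str]]:
        if self.stranded:
            if strand in ("+", "-"):
                return [(chrom, strand)]
            return [(chrom, "+"), (chrom, "-")]
        return [(chrom, ".")]

    def depth_array(self, chrom: str, strand: str = "any") -> np.ndarray:
        """Depth over a chromosome; strands summed when strand='any'."""
        size = self.chrom_sizes[chrom]
        out = np.zeros(size, dtype=np.int64)
        for key in self._keys(chrom, strand):
            if key in self.depth:
                out += self.depth[key]
        return out

    def mean_depth(self, region: Interval, strand: str = "any") -> float:
        arr = self.depth_array(region.chrom, strand)
        return float(arr[region.start : region.end].mean())

    def reads_overlapping(self, region: Interval, strand: str = "any") -> int:
        """Number of reads with >= 1 bp overlap with region."""
        n = 0
        for key in self._keys(region.chrom, strand):
            starts = self._read_starts.get(key)
            if starts is None:
                continue
            ends_sorted = np.sort(self._read_ends[key])
            # overlapping = total - (reads entirely right of region) - (entirely left)
            n_right = len(starts) - int(np.searchsorted(starts, region.end, side="left"))
            n_left = int(np.searchsorted(ends_sorted, region.start, side="right"))
            n += len(starts) - n_right - n_left
        return n

    def start_point_coords(self, region: Interval, strand: str = "any") -> set[int]:
        """Distinct 5' coordinates of reads overlapping the region."""
        coords: set[int] = set()
        for key in self._keys(region.chrom, strand):
            starts = self._read_starts.get(key)
            if starts is None:
                continue
            ends = self._read_ends[key]
            fps = self._read_fps[key]
            # reads sorted by start; overlapping reads satisfy start < region.end and end > region.start
            hi = int(np.searchsorted(starts, region.end, side="left"))
            sel = ends[:hi] > region.start
            coords.update(int(c) for c in fps[:hi][sel])
        return coords

    def start_points_in(self, region: Interval, strand: str = "any") -> int:
        return len(self.start_point_coords(region, strand))


def coverage_track(
    reads: list[AlignedRead], chrom_sizes: dict[str, int], stranded: bool = False
) -> CoverageTrack:
    """Build per-base depth and start-point sets from aligned reads.

    Depth at base b counts reads (all aligned blocks) containing b; the 5'
    start of a '+' read is its leftmost base, of a '-' read its rightmost.
    """
    track = CoverageTrack(chrom_sizes=dict(chrom_sizes), stranded=stranded)
    buckets: dict[tuple[str, str], list[AlignedRead]] = {}
    for r in reads:
        size = chrom_sizes.get(r.chrom)
        iv = r.interval
        if size is None or iv.end > size or r.start < 0:
            raise CoverageError(f"read {r.chrom}:{r.start}-{iv.end} out of chromosome bounds")
        key = (r.chrom, r.strand if stranded else ".")
        buckets.setdefault(key, []).append(r)
    for key, rs in buckets.items():
        chrom = key[0]
        size = chrom_sizes[chrom]
        diff = np.zeros(size + 1, dtype=np.int64)
        sps: dict[int, int] = {}
        for r in rs:
            for s, e in r.all_blocks():
                diff[s] += 1
                diff[e] -= 1
            fp = r.five_prime
            sps[fp] = sps.get(fp, 0) + 1
        track.depth[key] = np.cumsum(diff[:-1])
        track.start_points[key] = sps
        order = sorted(rs, key=lambda r: r.start)
        track._read_starts[key] = np.array([r.start for r in order], dtype=np.int64)
        track._read_ends[key] = np.array([r.interval.end for r in order], dtype=np.int64)
        track._read_fps[key] = np.array([r.five_prime for r in order], dtype=np.int64)
    track.total_mapped_reads = len(reads)
    return track


@dataclass(frozen=True)
class CoveredSegment:
    """A maximal run of bases at depth >= the threshold used to call it."""

    interval: Interval
    mean_depth: float
    n_reads: int
    n_start_points: int


def covered_segments(
    track: CoverageTrack, min_depth: int = 1, strand: str = "any"
) -> list[CoveredSegment]:
    """Maximal runs of bases with depth >= min_depth, annotated with read stats."""
    out: list[CoveredSegment] = []
    for chrom in sorted(track.chrom_sizes):
        arr = track.depth_array(chrom, strand)
        for start, end in _runs(arr >= min_depth):
            iv = Interval(chrom, start, end, ".")
            out.append(
                CoveredSegment(
                    interval=iv,
                    mean_depth=float(arr[start:end].mean()),
                    n_reads=track.reads_overlapping(iv, strand),
                    n_start_points=track.start_points_in(iv, strand),
                )
            )
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array as (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def start_point_count(
    reads: list[AlignedRead], region: Interval, strand: str = "any"
) -> int:
    """Distinct 5' start coordinates of reads overlapping the region."""
    coords = set()
    for r in reads:
        if r.chrom != region.chrom:
            continue
        if strand in ("+", "-") and r.strand != strand:
            continue
        iv = r.interval
        if iv.start < region.end and region.start < iv.end:
            coords.add(r.five_prime)
    return len(coords)


def write_bedgraph(track: CoverageTrack, prefix: str) -> list[str]:
    """Emit fixed 4-column bedGraph, one file per strand for stranded tracks.

    Minus-strand depths are written as given (not negated); no track lines.
    """
    paths = []
    strands = ("+", "-") if track.stranded else (".",)
    names = {"+": "plus", "-": "minus", ".": "all"}
    for strand in strands:
        path = f"{prefix}.{names[strand]}.bedGraph"
        with open(path, "w") as fh:
            for chrom in sorted(track.chrom_sizes):
                arr = track.depth_array(chrom, strand if strand != "." else "any")
                if not arr.any():
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts.tolist(), ends.tolist()):
                    v = int(arr[s])
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
        paths.append(path)
    return paths
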