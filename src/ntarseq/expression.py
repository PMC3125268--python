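"""Gene-level FPKM quantification, presence calls, tissue-enhancement and 5'-3' bias profiles.

FPKM here is the direct union-exon formula: reads overlapping any exonic
base of the (condensed) gene model, per kilobase of exonic model, per
million mapped reads.  No isoform deconvolution is attempted — presence
and fold-change logic operate at the condensed-gene level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import CondensedGene, Interval, Transcript
from .coverage import CoverageTrack

PRESENCE_FPKM = 0.01
MIN_START_POINTS = 2
DEFAULT_LENGTH_CLASSES_KB = (1.0, 2.0, 5.0)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionRecord:
    """Per-unit, per-tissue quantification with the presence call."""

    unit_id: str
    tissue: str
    fpkm: float
    n_reads: int
    n_start_points: int
    present: bool


@dataclass
class EnhancementCall:
    unit_id: str
    fpkm_a: float
    fpkm_b: float
    enhanced_in: str  # 'A' | 'B' | 'neither'


@dataclass
class BiasProfile:
    """Relative coverage along the 5'->3' axis for one transcript-length class."""

    length_class: str
    relative_coverage: np.ndarray  # length n_bins, max = 1


def assigned_reads(unit: CondensedGene | Transcript, track: CoverageTrack) -> int:
    """Reads overlapping >= 1 exonic base of the unit (union-exon assignment).

    Per-exon overlap counts, corrected for contiguous reads spanning the
    intron between consecutive exons (counted once per bridged pair).
    """
    n = 0
    exons = unit.exons
    for e in exons:
        n += track.reads_overlapping(e)
    for a, b in zip(exons, exons[1:]):
        bridge = Interval(a.chrom, a.end - 1, b.start + 1, ".")
        n -= _reads_containing_span(track, bridge)
    return n


def _reads_containing_span(track: CoverageTrack, bridge: Interval) -> int:
    """Reads whose interval covers the whole bridge (hence both flanking exons)."""
    n = 0
    for key in track._keys(bridge.chrom):
        starts = track._read_starts.get(key)
        if starts is None:
            continue
        ends = track._read_ends[key]
        hi = int(np.searchsorted(starts, bridge.start, side="right"))
        n += int(np.count_nonzero(ends[:hi] >= bridge.end))
    return n


def fpkm(
    unit: CondensedGene | Transcript, track: CoverageTrack, total_mapped: int | None = None
) -> float:
    """Fragments per kilobase of exonic model per million mapped fragments."""
    total = track.total_mapped_reads if total_mapped is None else total_mapped
    if total <= 0:
        raise ExpressionError("total mapped read count must be positive")
    n = assigned_reads(unit, track)
    kb = unit.exonic_length / 1000.0
    return n / (kb * total / 1e6)


def call_present(
    fpkm_value: float, n_start_points: int,
    threshold: float = PRESENCE_FPKM, min_sp: int = MIN_START_POINTS,
) -> bool:
    """Present iff FPKM strictly exceeds the threshold and SPs rule out clonality."""
    return fpkm_value > threshold and n_start_points >= min_sp


def quantify(
    units: list[CondensedGene] | list[Transcript],
    track: CoverageTrack,
    tissue: str,
    threshold: float = PRESENCE_FPKM,
    min_sp: int = MIN_START_POINTS,
) -> list[ExpressionRecord]:
    """FPKM + presence call for every unit against one tissue's screening track."""
    out = []
    for u in units:
        uid = u.gene_symbol if isinstance(u, CondensedGene) else u.id
        n = assigned_reads(u, track)
        f = n / ((u.exonic_length / 1000.0) * track.total_mapped_reads / 1e6)
        coords: set[int] = set()
        for e in u.exons:
            coords |= track.start_point_coords(e)
        sp = len(coords)
        out.append(ExpressionRecord(uid, tissue, f, n, sp, call_present(f, sp, threshold, min_sp)))
    return out


def tissue_enhanced(
    fpkm_a: float, fpkm_b: float, fold: float = 3.0, penalty: float = 1.0
) -> bool:
    """True iff tissue A's FPKM exceeds ``fold`` times tissue B's penalized FPKM.

    The +1 penalty damps spurious folds of rare transcripts: a/(b+1) >= fold.
    """
    if fpkm_a < 0 or fpkm_b < 0:
        raise ExpressionError("FPKM values must be non-negative")
    return fpkm_a / (fpkm_b + penalty) >= fold


def enhancement_call(
    unit_id: str, fpkm_a: float, fpkm_b: float, fold: float = 3.0, penalty: float = 1.0
) -> EnhancementCall:
    if tissue_enhanced(fpkm_a, fpkm_b, fold, penalty):
        status = "A"
    elif tissue_enhanced(fpkm_b, fpkm_a, fold, penalty):
        status = "B"
    else:
        status = "neither"
    return EnhancementCall(unit_id, fpkm_a, fpkm_b, status)


def _length_class_label(length: int, edges_kb: tuple[float, ...]) -> str:
    prev = 0.0
    for e in edges_kb:
        if length <= e * 1000:
            return f"({prev:g},{e:g}] kb" if prev else f"<={e:g} kb"
        prev = e
    return f">{prev:g} kb"


def bias_profile(
    units: list[CondensedGene] | list[Transcript],
    track: CoverageTrack,
    length_class_edges_kb: tuple[float, ...] = DEFAULT_LENGTH_CLASSES_KB,
    n_bins: int = 100,
) -> list[BiasProfile]:
    """Length-normalized 5'->3' coverage profiles per transcript-length class.

    Each unit's per-base exonic depth is laid along its 5'->3' axis
    (genome order reversed for '-' strand units), averaged into ``n_bins``
    equal-width bins, summed within the length class and scaled so the
    class maximum equals 1.
    """
    if n_bins < 10:
        raise ExpressionError("n_bins must be >= 10")
    sums: dict[str, np.ndarray] = {}
    labels_in_order: list[str] = []
    prev = 0.0
    for e in length_class_edges_kb:
        labels_in_order.append(_length_class_label(int(e * 1000), length_class_edges_kb))
        prev = e
    labels_in_order.append(f">{prev:g} kb")
    for u in units:
        arrs = []
        for e in u.exons:
            arrs.append(track.depth_array(e.chrom)[e.start : e.end])
        per_base = np.concatenate(arrs).astype(float)
        if u.strand == "-":
            per_base = per_base[::-1]
        binned = _bin_means(per_base, n_bins)
        label = _length_class_label(len(per_base), length_class_edges_kb)
        if label not in sums:
            sums[label] = np.zeros(n_bins)
        sums[label] += binned
    out = []
    for label in labels_in_order:
        if label not in sums:
            warnings.warn(f"length class {label} is empty; profile omitted", stacklevel=2)
            continue
        total = sums[label]
        peak = total.max()
        rel = total / peak if peak > 0 else total
        out.append(BiasProfile(label, rel))
    return out


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of ``values`` over n_bins equal-width windows along its index axis."""
    idx = np.floor(np.arange(len(values)) * n_bins / len(values)).astype(int)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return means


def write_expression_tsv(records: list[ExpressionRecord], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "tissue": r.tissue,
                "fpkm": r.fpkm,
                "n_reads": r.n_reads,
                "n_sp": r.n_start_points,
                "present": int(r.present),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_bias_tsv(profiles: list[BiasProfile], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("length_class\tbin\trelative_coverage\n")
        for p in profiles:
            for i, v in enumerate(p.relative_coverage):
                fh.write(f"{p.length_class}\t{i}\t{v:.6f}\n")
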