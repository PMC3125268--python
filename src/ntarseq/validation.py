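"""Strand-aware confirmation of nTAR candidates and downstream summaries.

The validation protocol supplies stranded reads: a candidate is
confirmed when at least ``min_reads`` validation reads overlap it, and
its orientation (sense/antisense relative to the related gene) is called
only when every supporting read agrees.  Further summaries: per-class
sense/antisense ratios, detection ratios versus the related gene,
gene-corrected differential calls across tissues, and confirmation of
3' ends by poly-A anchored tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .annotation import CondensedGene, Interval
from .coverage import AlignedRead, CoverageTrack
from .discovery import NtarCandidate, NtarClass

CONFIRM_MIN_READS = 3
DETECTION_RATIO_BIN = 0.25


class ValidationError(ValueError):
    pass


@dataclass
class ValidatedNtar:
    candidate: NtarCandidate
    ntar_class: NtarClass
    confirmed: bool
    sense_reads: int
    antisense_reads: int
    orientation: str  # sense | antisense | ambiguous | undetermined
    detection_ratio: float | None = None
    detection_ratio_bin: str | None = None
    polyA_confirmed: bool = False


@dataclass
class ClassOrientationSummary:
    ntar_class: str
    n_sense: int
    n_antisense: int
    ratio: float  # inf when n_antisense == 0


@dataclass
class DifferentialNtar:
    ntar_id: str
    cov_a: float
    cov_b: float
    gene_fold: float  # A-vs-B directional fold of the related gene (1 for NGA)
    corrected_fold: float  # >= fold: up in A; <= 1/fold: up in B
    differential: bool


def _overlapping_by_strand(
    reads: list[AlignedRead], region: Interval
) -> tuple[int, int]:
    plus = minus = 0
    for r in reads:
        if r.chrom != region.chrom:
            continue
        iv = r.interval
        if iv.start < region.end and region.start < iv.end:
            if r.strand == "+":
                plus += 1
            else:
                minus += 1
    return plus, minus


def validate_ntar(
    cand: NtarCandidate,
    ntar_class: NtarClass,
    stranded_reads: list[AlignedRead],
    min_reads: int = CONFIRM_MIN_READS,
) -> ValidatedNtar:
    """Count stranded validation reads over the candidate and call orientation.

    Sense = same strand as the related gene.  NGA candidates have no
    reference strand: counts are kept on genomic +/- (reported in the
    sense/antisense slots) but orientation stays 'undetermined'.
    """
    plus, minus = _overlapping_by_strand(stranded_reads, cand.interval)
    if ntar_class.related_gene is None:
        sense, antisense = plus, minus  # genomic-strand bookkeeping only
        orientation = "undetermined"
    else:
        if ntar_class.related_gene.strand == "+":
            sense, antisense = plus, minus
        else:
            sense, antisense = minus, plus
        if sense > 0 and antisense == 0:
            orientation = "sense"
        elif antisense > 0 and sense == 0:
            orientation = "antisense"
        elif sense and antisense:
            orientation = "ambiguous"
        else:
            orientation = "undetermined"
    confirmed = sense + antisense >= min_reads
    return ValidatedNtar(cand, ntar_class, confirmed, sense, antisense, orientation)


def class_orientation_summary(
    validated: list[ValidatedNtar],
) -> list[ClassOrientationSummary]:
    """Per-class counts of purely-sense vs purely-antisense confirmed nTARs.

    Ambiguous (mixed-strand) and undetermined (NGA) calls are excluded,
    mirroring the "unambiguous orientation only" convention.
    """
    per: dict[str, list[int]] = {}
    for v in validated:
        if not v.confirmed or v.orientation not in ("sense", "antisense"):
            continue
        a = per.setdefault(v.ntar_class.label, [0, 0])
        if v.orientation == "sense":
            a[0] += 1
        else:
            a[1] += 1
    out = []
    for label in sorted(per):
        n_s, n_a = per[label]
        ratio = n_s / n_a if n_a else math.inf
        out.append(ClassOrientationSummary(label, n_s, n_a, ratio))
    return out


def detection_ratio(
    cand: NtarCandidate,
    related_gene: CondensedGene | None,
    screening_track: CoverageTrack,
) -> tuple[float | None, str]:
    """Mean per-base depth of the nTAR over that of the related gene's exons.

    Returns ``(ratio, bin_label)``; for an unexpressed related gene the
    ratio is None with the special bin 'related gene not expressed'.
    Raises for NGA input (no related gene exists).
    """
    if related_gene is None:
        raise ValidationError("detection_ratio is undefined for NGA candidates")
    ntar_depth = screening_track.mean_depth(cand.interval)
    exonic = sum(
        float(screening_track.depth_array(e.chrom)[e.start : e.end].sum())
        for e in related_gene.exons
    )
    gene_depth = exonic / related_gene.exonic_length
    if gene_depth == 0:
        return None, "related gene not expressed"
    ratio = ntar_depth / gene_depth
    return ratio, _ratio_bin(ratio)


def _ratio_bin(ratio: float, width: float = DETECTION_RATIO_BIN) -> str:
    if ratio <= width:
        return f"<={width:g}"
    if ratio > 1.0:
        return ">1"
    lo = math.floor((ratio - 1e-12) / width) * width
    return f"({lo:g},{lo + width:g}]"


def _directional_fold(x: float, y: float, penalty: float) -> float:
    return x / (y + penalty)


def differential_ntar(
    ntar_id: str,
    cov_a: float,
    cov_b: float,
    gene_fpkm_a: float | None,
    gene_fpkm_b: float | None,
    fold: float = 3.0,
    penalty: float = 1.0,
) -> DifferentialNtar:
    """Gene-corrected cross-tissue fold change of an nTAR.

    Directional folds use the penalized form x/(y+penalty) for both the
    nTAR (mean depth) and the related gene (FPKM); the nTAR fold is then
    divided by the gene fold per direction.  Gene FPKMs of None (NGA)
    mean no correction.  A zero gene fold against a positive nTAR fold
    yields an infinite corrected fold (differential); 0/0 yields 1.
    """
    ntar_ab = _directional_fold(cov_a, cov_b, penalty)
    ntar_ba = _directional_fold(cov_b, cov_a, penalty)
    if gene_fpkm_a is None or gene_fpkm_b is None:
        gene_ab = gene_ba = 1.0
    else:
        gene_ab = _directional_fold(gene_fpkm_a, gene_fpkm_b, penalty)
        gene_ba = _directional_fold(gene_fpkm_b, gene_fpkm_a, penalty)
    c_ab = _corrected(ntar_ab, gene_ab)
    c_ba = _corrected(ntar_ba, gene_ba)
    differential = c_ab >= fold or c_ba >= fold
    corrected = c_ab if c_ab >= c_ba else (1.0 / c_ba if c_ba > 0 else 1.0)
    gene_fold = gene_ab
    return DifferentialNtar(ntar_id, cov_a, cov_b, gene_fold, corrected, differential)


def _corrected(ntar_fold: float, gene_fold: float) -> float:
    if gene_fold == 0:
        return math.inf if ntar_fold > 0 else 1.0
    return ntar_fold / gene_fold


def confirm_polyA(
    cand: NtarCandidate,
    polyA_tags: list[AlignedRead],
    related_gene: CondensedGene | None = None,
    min_tags: int = 1,
) -> tuple[bool, str]:
    """Confirm a 3' end: >= min_tags tags whose 3'-anchored end lies inside the nTAR.

    The anchored end is the tag's 3'-most aligned base.  Tag orientation is
    reported relative to the related gene ('sense'/'antisense'), or as the
    genomic strand for NGA.
    """
    iv = cand.interval
    n = 0
    strands: set[str] = set()
    for t in polyA_tags:
        if t.chrom != iv.chrom:
            continue
        anchor = t.interval.end - 1 if t.strand == "+" else t.start  # 3'-most aligned base
        if iv.start <= anchor < iv.end:
            n += 1
            strands.add(t.strand)
    confirmed = n >= min_tags
    if not confirmed or not strands:
        return confirmed, "none"
    if len(strands) > 1:
        return confirmed, "mixed"
    (s,) = strands
    if related_gene is None:
        return confirmed, s
    return confirmed, "sense" if s == related_gene.strand else "antisense"


def write_validated_tsv(validated: list[ValidatedNtar], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tclass\trelated_gene\tdistance\tmean_depth\tn_reads\tn_sp"
            "\tconfirmed\tsense_reads\tantisense_reads\torientation"
            "\tdetection_ratio\tdetection_ratio_bin\tpolyA_confirmed\n"
        )
        for v in validated:
            c, k = v.candidate, v.ntar_class
            sym = k.related_gene.gene_symbol if k.related_gene else "."
            ratio = "" if v.detection_ratio is None else f"{v.detection_ratio:.4f}"
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t{k.label}\t{sym}"
                f"\t{k.distance}\t{c.mean_depth:.3f}\t{c.n_reads}\t{c.n_start_points}"
                f"\t{int(v.confirmed)}\t{v.sense_reads}\t{v.antisense_reads}\t{v.orientation}"
                f"\t{ratio}\t{v.detection_ratio_bin or ''}\t{int(v.polyA_confirmed)}\n"
            )


def write_validated_bed(validated: list[ValidatedNtar], path: str) -> None:
    """BED6; strand column carries the orientation call mapped onto the genome."""
    with open(path, "w") as fh:
        for v in validated:
            c, k = v.candidate, v.ntar_class
            sym = k.related_gene.gene_symbol if k.related_gene else "."
            if v.orientation in ("sense", "antisense") and k.related_gene is not None:
                g = k.related_gene.strand
                strand = g if v.orientation == "sense" else ("-" if g == "+" else "+")
            else:
                strand = "."
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{k.label}:{sym}\t{round(c.mean_depth)}\t{strand}\n"
            )
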